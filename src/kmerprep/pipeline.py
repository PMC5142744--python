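"""The end-to-end pre-filtering pipeline used for acceptance-style testing.

Chains the library stages a user would run on raw reads before handing them
to an assembler: quality filtering, whole-set k-mer counting, low-abundance
error trimming, then digital normalization.  Each intermediate is written to
the working directory and a JSON summary records per-stage read counts and
retention fractions.

"Approximately the expected results" is made operational: the package ships
tolerance bands on per-stage retention (``data/retention_bands.json``,
pre-computed from seeded development simulations at the default settings),
and :func:`check_retention` reports any stage falling outside its band.
Outputs are a pure function of the input bytes and parameters, so re-running
in a clean directory reproduces them byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .countmin import CountMinSketch
from .diginorm import DiginormParams, normalize_by_median
from .filtering import TrimParams, filter_abund, quality_filter
from .kmer_core import HashFamily, KmerSpec
from .seqio import read_records, write_records

__all__ = ["PipelineParams", "run_pipeline", "check_retention", "load_default_bands"]


@dataclass(frozen=True)
class PipelineParams:
    k: int = 20
    min_mean_q: float = 20.0
    trim_cutoff: int = 2
    norm_cutoff: int = 20
    n_tables: int = 4
    table_size: int = 1_000_000


def run_pipeline(input_path, workdir, params: PipelineParams = PipelineParams()) -> dict:
    """Run quality-filter -> count -> filter-abund -> normalize-by-median.

    Writes ``01_quality.fq``, ``counts.mkm``, ``02_trimmed.fq``,
    ``03_normalized.fq`` and ``summary.json`` under ``workdir`` and returns
    the summary dict.  Any stage failure propagates as an exception, leaving
    the outputs of completed stages in place.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    spec = KmerSpec(k=params.k, canonical=True)
    stages = []

    raw = list(read_records(input_path))

    qf = quality_filter(raw, min_mean_q=params.min_mean_q, min_len=params.k)
    write_records(qf, workdir / "01_quality.fq", format="fastq")
    stages.append(_stage("quality_filter", len(raw), len(qf)))

    sketch = CountMinSketch(spec, HashFamily.from_request(params.table_size, params.n_tables))
    for rec in qf:
        sketch.consume_sequence(rec.sequence)
    sketch.save(workdir / "counts.mkm")

    trimmed, trim_report = filter_abund(qf, sketch, TrimParams(min_count=params.trim_cutoff))
    write_records(trimmed, workdir / "02_trimmed.fq", format="fastq")
    stages.append(_stage("abundance_trim", len(qf), len(trimmed)))

    norm_params = DiginormParams(
        cutoff=params.norm_cutoff, spec=spec,
        n_tables=params.n_tables, table_size=params.table_size,
    )
    kept, norm_report = normalize_by_median(trimmed, norm_params)
    write_records(kept, workdir / "03_normalized.fq", format="fastq")
    stages.append(_stage("digital_normalization", len(trimmed), len(kept)))

    summary = {
        "n_input_reads": len(raw),
        "n_output_reads": len(kept),
        "n_reads_trimmed": trim_report.n_trimmed,
        "stages": stages,
    }
    (workdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _stage(name: str, n_in: int, n_out: int) -> dict:
    return {
        "name": name,
        "n_in": n_in,
        "n_out": n_out,
        "retention": (n_out / n_in) if n_in else None,
    }


def load_default_bands() -> dict:
    """Shipped per-stage retention bands for the default parameters."""
    with resources.files("kmerprep.data").joinpath("retention_bands.json").open() as fh:
        return json.load(fh)


def check_retention(summary: dict, bands: dict | None = None) -> list[str]:
    """Return a list of band violations ('' empty means all stages in band).

    Stages with no input reads are skipped (an empty pipeline is vacuously
    in band).  Stages without a shipped band are ignored.
    """
    if bands is None:
        bands = load_default_bands()
    problems = []
    for stage in summary["stages"]:
        band = bands.get(stage["name"])
        if band is None or stage["retention"] is None:
            continue
        lo, hi = band
        if not lo <= stage["retention"] <= hi:
            problems.append(
                f"{stage['name']}: retention {stage['retention']:.3f} outside [{lo}, {hi}]"
            )
    return problems
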