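If you use kmerprep in work that leads to a publication, please cite the
software by name and version, for example:

    kmerprep version 1.0.0: k-mer based pre-filtering for DNA sequencing
    reads (CountMin-sketch counting, digital normalization, abundance
    trimming, and read partitioning). The kmerprep developers.

The version string is printed by `kmerprep --version` and by the citation
epilog that every command writes to standard error. Citing the exact version
matters: the command-line interface is semantically versioned, and results
can differ across major versions.

The algorithms implemented here (CountMin-sketch k-mer counting, Bloom-filter
k-mer graphs, and digital normalization) originate in the bioinformatics
methods literature; please also cite the original method publications
appropriate to the analysis you performed.
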