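usage: kmerprep simulate [-h] --length LENGTH [--coverage COVERAGE]
                         [--read-length READ_LENGTH] [--error-rate ERROR_RATE]
                         [--seed SEED] [--circular] -o OUT.fq

options:
  -h, --help            show this help message and exit
  --length LENGTH       genome length (bases)
  --coverage COVERAGE   fold coverage (default 20)
  --read-length READ_LENGTH
                        read length (default 100)
  --error-rate ERROR_RATE
                        per-base substitution probability (default 0)
  --seed SEED           random seed (default 0)
  --circular            sample reads from a circular genome (uniform edge
                        coverage)
  -o OUT.fq             output FASTQ file
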