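usage: kmerprep partition [-h] [-k K] [-N N] [-x X] -o OUT.tsv INPUT

positional arguments:
  INPUT       input reads file

options:
  -h, --help  show this help message and exit
  -k K        k-mer length (default 20)
  -N N        number of bit tables (default 4)
  -x X        approximate table size in bits (default 1000000)
  -o OUT.tsv  output TSV (read_id<TAB>partition_id)
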