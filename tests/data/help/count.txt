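usage: kmerprep count [-h] [-k K] [-N N] [-x X] -o SKETCH INPUT [INPUT ...]

positional arguments:
  INPUT       FASTA/FASTQ file(s)

options:
  -h, --help  show this help message and exit
  -k K        k-mer length (default 20)
  -N N        number of sketch tables (default 4)
  -x X        approximate table size (default 1000000)
  -o SKETCH   output sketch file
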