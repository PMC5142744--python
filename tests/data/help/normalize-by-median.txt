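usage: kmerprep normalize-by-median [-h] [-C C] [-k K] [-N N] [-x X]
                                    [--savetable F] [--loadtable F] -o OUT
                                    INPUT

positional arguments:
  INPUT          input reads file

options:
  -h, --help     show this help message and exit
  -C C           coverage cutoff (default 20)
  -k K           k-mer length (default 20)
  -N N           number of sketch tables (default 4)
  -x X           approximate table size (default 1000000)
  --savetable F  save the counting table afterwards
  --loadtable F  resume from a saved counting table
  -o OUT         output reads file
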