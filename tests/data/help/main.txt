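usage: kmerprep [-h] [--version] COMMAND ...

Command-line interface: the stable, semantically-versioned surface.

positional arguments:
  COMMAND
    count              count k-mers from reads into a sketch file
    abund-dist         histogram of distinct k-mer abundances
    normalize-by-median
                       digital normalization to a median coverage cutoff
    filter-abund       trim reads at low-abundance k-mers
    quality-filter     drop reads by mean quality and length
    partition          assign reads to k-mer connectivity partitions
    simulate           simulate a random genome and shotgun reads

options:
  -h, --help           show this help message and exit
  --version            show program's version number and exit
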