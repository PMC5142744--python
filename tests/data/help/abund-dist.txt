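usage: kmerprep abund-dist [-h] SKETCH INPUT OUT.tsv

positional arguments:
  SKETCH      sketch file from 'count'
  INPUT       reads the sketch was built from
  OUT.tsv     output TSV (abundance<TAB>count)

options:
  -h, --help  show this help message and exit
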