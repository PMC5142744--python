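usage: kmerprep filter-abund [-h] [-C C] [--min-length MIN_LENGTH] -o OUT
                             SKETCH INPUT

positional arguments:
  SKETCH                sketch file from 'count'
  INPUT                 input reads file

options:
  -h, --help            show this help message and exit
  -C C                  abundance cutoff (default 2)
  --min-length MIN_LENGTH
                        minimum surviving read length (default: k)
  -o OUT                output reads file
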