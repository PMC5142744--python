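usage: kmerprep quality-filter [-h] [--min-mean-q MIN_MEAN_Q]
                               [--min-len MIN_LEN] -o OUT
                               INPUT

positional arguments:
  INPUT                 input FASTQ file

options:
  -h, --help            show this help message and exit
  --min-mean-q MIN_MEAN_Q
                        minimum mean Phred quality (default 20)
  --min-len MIN_LEN     minimum read length (default 1)
  -o OUT                output reads file
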