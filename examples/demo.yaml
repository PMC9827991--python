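# Demo: 200-kb genome with a 500-unit 70/30 TTTAGGG/TTCAGGG array, 20k skim reads
genome_length_bp: 200000
background_gc: 0.40
arrays:
  - position: 50000
    length_units: 500
    variant_props: {TTTAGGG: 0.7, TTCAGGG: 0.3}
    interspersion: iid
n_reads: 20000
read_length: 150
error_rate: 0.0
genome_size_Mb_1C: 500.0
seed: 20221011
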