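>A name=NFKB weight=6
GGGACTTTCC
>B name=NFAT weight=2
GGAAAATTTC
>C name=AP1 weight=2
TGACTCA
>D name=CREB weight=2
TGACGTCAGC
>E name=STAT5 weight=2
TTCCAAGAAC
>F name=ISRE weight=2
AGTTTCACTTTC
>G name=RUNX weight=2
ATGTGGTTTG
>H name=EGR1 weight=2
GCGTGGGCG
>I name=ETS weight=2
ACAGGAAGTG
>J name=OCT weight=2
TATGCAAATC
>K name=SRE weight=2
CCATATTTGG
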