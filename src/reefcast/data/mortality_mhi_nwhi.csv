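# Synthetic DHM/mortality observation fixture. The underlying bleaching-event
# coordinates are not tabulated in any packaged source; these points emulate
# the documented qualitative ordering (Caribbean 2005 steeper than Hawaiian
# events) and are non-authoritative.
dhm,mortality_fraction,source_label
6.7,0.4026,NWHI02
7.13,0.4624,MHI77
8.76,0.6324,NWHI04
7.11,0.4436,NWHI02
5.23,0.2666,MHI72
8.06,0.5596,MHI77
2.38,0.0691,MHI77
1.05,0.0137,MHI77
6.02,0.3366,MHI96
6.45,0.3858,MHI72
5.96,0.3221,NWHI04
3.61,0.1499,NWHI02
8.37,0.5767,MHI72
6.92,0.4367,NWHI04
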