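# Synthetic DHM/mortality observation fixture. The underlying bleaching-event
# coordinates are not tabulated in any packaged source; these points emulate
# the documented qualitative ordering (Caribbean 2005 steeper than Hawaiian
# events) and are non-authoritative.
dhm,mortality_fraction,source_label
2.06,0.078,Carib05
2.91,0.1544,Carib05
7.42,0.8767,Carib05
6.15,0.6293,Carib05
7.49,0.8526,Carib05
7.4,0.8535,Carib05
6.01,0.6041,Carib05
2.31,0.1578,Carib05
7.89,0.9304,Carib05
5.61,0.5258,Carib05
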