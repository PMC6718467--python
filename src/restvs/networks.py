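"""Functional network labels used to group ROIs.

Seven cortical networks — visual (VI), somato-motor (SM), dorsal attention
(DA), ventral attention (VA), fronto-temporal (FT), fronto-parietal (FP) and
default mode (DM) — plus two anatomical groups, basal ganglia (BG) and
cerebellum (CB).
"""

NETWORKS: tuple[str, ...] = ("VI", "SM", "DA", "VA", "FT", "FP", "DM", "BG", "CB")
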