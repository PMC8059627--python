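{
  "protein_id": "Q13402",
  "protein_length": 2215,
  "version": 1,
  "comment": "Human unconventional myosin VIIa (MYO7A) domain architecture. 1-based inclusive UniProt coordinates. Nested motifs (ATP-binding, actin-binding, single alpha-helix) carry a parent and take precedence over it for residue assignment.",
  "regions": [
    {"name": "Motor domain", "start": 65, "end": 741, "parent": null},
    {"name": "ATP-binding motif", "start": 158, "end": 165, "parent": "Motor domain"},
    {"name": "Actin-binding", "start": 632, "end": 639, "parent": "Motor domain"},
    {"name": "IQ1", "start": 745, "end": 765, "parent": null},
    {"name": "IQ2", "start": 768, "end": 788, "parent": null},
    {"name": "IQ3", "start": 791, "end": 811, "parent": null},
    {"name": "IQ4", "start": 814, "end": 834, "parent": null},
    {"name": "IQ5", "start": 837, "end": 857, "parent": null},
    {"name": "coiled coil", "start": 858, "end": 1016, "parent": null},
    {"name": "single α-helix", "start": 858, "end": 935, "parent": "coiled coil"},
    {"name": "MyTH-1", "start": 1017, "end": 1253, "parent": null},
    {"name": "FERM-1", "start": 1258, "end": 1602, "parent": null},
    {"name": "SH3", "start": 1603, "end": 1672, "parent": null},
    {"name": "MyTH-2", "start": 1747, "end": 1896, "parent": null},
    {"name": "FERM-2", "start": 1902, "end": 2205, "parent": null}
  ]
}
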