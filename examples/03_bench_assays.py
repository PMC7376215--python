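"""Bench-assay quantification: IP efficiency, dot-blot linearity,
RT-truncation index and loading-normalized densitometry.
"""

from oxrip import dotblot_linearity, ip_efficiency, loading_normalize, truncation_index

# immunoprecipitation efficiency from scintillation counts of radiolabeled oligos
eff = ip_efficiency(eluted_counts=300, input_counts=1000, background_counts=50)
print(f"IP efficiency: {eff['efficiency_percent']:.1f}% (clipped: {eff['clipped']})")

# dose linearity of antibody binding vs number of 8-oxoG marks per oligo
fit = dotblot_linearity([0, 1, 2, 4], [2.0, 11.5, 21.0, 40.5])
print(f"dot blot: slope={fit['slope']:.2f} signal/mark, R^2={fit['r_squared']:.4f} "
      "(R^2 near 1 means little sequence bias)")

# reverse-transcription truncation: oxidation depletes the distal product
bands = {
    "target_distal_exposed": 42.0, "target_proximal_exposed": 100.0,
    "target_distal_control": 95.0, "target_proximal_control": 100.0,
    "norm_distal_exposed": 98.0, "norm_proximal_exposed": 100.0,
    "norm_distal_control": 99.0, "norm_proximal_control": 100.0,
}
trunc = truncation_index(bands)
print(f"truncation: normalized distal/proximal exposed={trunc.ratio_exposed:.3f}, "
      f"control={trunc.ratio_control:.3f}; oxidation index={trunc.oxidation_index:.3f} "
      f"-> oxidized: {trunc.oxidized}")

# western densitometry: loading-normalized fold change, control over exposed
fold = loading_normalize(target_control=100, loading_control=50,
                         target_exposed=40, loading_exposed=50)
print(f"protein expression drop upon exposure: {fold:.2f}-fold (loading-normalized)")
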