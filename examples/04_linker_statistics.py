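"""Linker-length and phi-position statistics: tandem motif vs general C2H2.

Generates one dataset under each linker model (tandem: 11.8 +/- 4.4 aa;
background: 8.1 +/- 5.0 aa), recovers the linkers through the annotator,
and runs the comparison tests: Mann-Whitney U for the location shift,
F test for variance, chi-square for hydrophobic enrichment at phi1, and
the TGE(K/R)P carrier rate among background linkers.
"""

import numpy as np

from tcwch2 import (
    FrequencyTable,
    GeneratorConfig,
    annotate_tandems,
    chi2_vs_background,
    f_variance_test,
    generate_dataset,
    has_tgekp,
    linker_summary,
    mann_whitney,
    phi_frequency,
    sample_background_linkers,
)
from tcwch2.simulate import PHI_BACKGROUND_FREQS
from tcwch2.stats import PHI1_HYDROPHOBIC

lengths = {}
tandem_sets = {}
for name, builder, seed in (
    ("tandem", GeneratorConfig.tcwch2, 101),
    ("background", GeneratorConfig.background, 102),
):
    cfg = builder(seed=seed, n_records=3000)
    records, _ = generate_dataset(cfg)
    tandems = [annotate_tandems(r, cfg.scan_config)[0] for r in records]
    tandem_sets[name] = tandems
    lengths[name] = [t.linker_len for t in tandems]
    s = linker_summary(lengths[name])
    print(f"{name:10s} linkers: {s.mean:5.2f} +/- {s.sd:4.2f} aa  (n={s.n}, range {s.min}-{s.max})")

u = mann_whitney(lengths["tandem"], lengths["background"])
f = f_variance_test(lengths["tandem"], lengths["background"])
print(f"\nMann-Whitney U: U={u.statistic:.0f}, p {u.p_display}  (tandem linkers are longer)")
print(f"F test:         F={f.statistic:.2f}, p {f.p_display}  (variance ratio tandem/background)")

phi1, _ = phi_frequency(tandem_sets["tandem"])
chi = chi2_vs_background(phi1, FrequencyTable.from_freqs(PHI_BACKGROUND_FREQS), PHI1_HYDROPHOBIC)
vli = 100 * phi1.mass(PHI1_HYDROPHOBIC)
print(f"\nphi1 V+L+I share: {vli:.1f}% vs 19.0% background; chi2={chi.statistic:.0f}, p {chi.p_display}")

linkers = sample_background_linkers(2000, seed=103)
rate = 100 * np.mean([has_tgekp(s) for s in linkers])
print(f"TGE(K/R)P in background linkers: {rate:.1f}% (configured rate 65%)")

print("\nTandem linkers are significantly longer than general-C2H2 linkers,")
print("their phi positions are strongly hydrophobic-biased, and the")
print("canonical DNA-binding linker pentamer is a background-only feature.")
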