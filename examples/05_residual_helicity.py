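"""Residual helicity from circular dichroism at 222 nm.

Converts mean-residue ellipticity to fraction helix under standard
chain-length- and temperature-dependent baselines, round-tripping the
generator for a wild-type peptide at 17% helix and a glycine variant 3
points lower.
"""

from phibind import estimate_fraction_helix, generate_cd, make_panel
from phibind.synthetic_data import HelicityConfig

panel = make_panel(seed=1)
cfg = HelicityConfig()
cd = generate_cd(panel, cfg, seed=1).set_index("variant_id")

for vid in ("WT", "S132A", "S132G"):
    mre = cd.loc[vid, "mre_222"]
    f = estimate_fraction_helix(mre, cfg.n_residues, cfg.temperature, cfg.baselines)
    print(f"{vid:6s} MRE(222) = {mre:9.1f} deg cm^2 dmol^-1  ->  "
          f"fraction helix = {f:.3f}")
print("\nGly substitutions lower helicity by the configured 0.03; "
      "interface Ala variants by 0.01.")
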