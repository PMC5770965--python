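"""End-to-end phi-value analysis of a synthetic mutant panel.

Generates the default panel (interface alanine variants across both helices
and the kink, surface Ala/Gly pairs) with known ground truth, fits every
variant, and prints the phi report: per-variant free-energy changes from
both branches, averaged phi-values, the dual-branch 0.34 kcal/mol
reporting filter, and the per-region transition-state pattern.
"""

from phibind import generate_dataset, make_panel
from phibind.pipeline import RunConfig, fit_dataset, phi_report

panel = make_panel(seed=1)
dataset = generate_dataset(panel, seed=1)
records = fit_dataset(dataset)
tables = phi_report(records, RunConfig(seed=1))

truth = panel.truth_table().set_index("variant_id")
print(f"{'variant':8s} {'region':8s} {'ddG_eq':>7s} {'ddG_kin':>7s} "
      f"{'phi_avg':>8s} {'phi_true':>8s}  report  class")
for _, row in tables["phi"].iterrows():
    vid = row["variant_id"]
    print(f"{vid:8s} {row['region']:8s} {row['ddg_equb_kcal_mol']:7.2f} "
          f"{row['ddg_kin_kcal_mol']:7.2f} {row['phi_average']:8.3f} "
          f"{truth.loc[vid, 'phi_true']:8.3f}  {str(row['reportable']):6s} "
          f"{row['ts_class']}")

print("\nregion summary (reported phi-values only):")
print(tables["region_summary"].to_string(index=False))
print("\nlinear free-energy slopes (vs log Kd):")
print(tables["lfe_slopes"].to_string(index=False))
summary = tables["summary"].iloc[0]
print(f"\n{int(summary['n_reportable'])} phi-values reportable of "
      f"{int(summary['n_variants'])} variants; a negative-phi patch in the "
      "kink region marks candidate nonnative transition-state contacts.")
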