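"""Three-stage panel pipeline: simulate -> fit -> phi report.

The stages are plain functions over a shared :class:`RunConfig`, so real
experimental tables can replace the stage-1 output: anything that produces
the per-variant rate/equilibrium table in the documented format can feed
the phi stage.  Every stage writes its config snapshot next to its outputs
and logs per-variant events (fit flags, exclusions) — a panel narrative
hinges on which variants were dropped and why.

Re-running any stage on unchanged inputs with an unchanged config yields
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .equilibrium_binding import EquilibriumResult, TitrationCurve, fit_anisotropy_isotherm
from .kinetic_model import Trace
from .measurement import Measurement
from .phi_analysis import (
    ClassificationThresholds,
    PhiResult,
    RateFitResult,
    VariantRecord,
    apply_consistency,
    apply_report_filter,
    classify_panel,
    compare_kd,
    composite_ala_gly,
    lfe_table,
    phi_for_variant,
    region_summary,
)
from .synthetic_data import (
    AcquisitionConfig,
    Dataset,
    PanelConfig,
    generate_dataset,
    make_panel,
)
from .trace_fitting import (
    CompetitionSeries,
    fit_association_series,
    fit_dissociation_asymptote,
    fit_trace_auto,
    summarize_slow_phase,
)

logger = logging.getLogger("phibind")

__all__ = [
    "RunConfig",
    "run_simulate",
    "run_fit",
    "fit_dataset",
    "run_phi",
    "phi_report",
]


@dataclass
class RunConfig:
    """Run-level configuration shared by all stages.

    ``temperature`` defaults to 298.15 K as a documented convention — it is
    a required experimental input, not a derived value.  The ddG reporting
    threshold, branch-consistency tolerance and classification bands are
    the reporting conventions of the analysis and are serialized alongside
    every output.
    """

    temperature: float = 298.15
    ddg_threshold: float = 0.34  # kcal/mol, dual-branch reporting filter
    consistency_tolerance: float = 2.0  # multiples of combined SE
    classification: ClassificationThresholds = field(
        default_factory=ClassificationThresholds
    )
    seed: int = 0
    panel: PanelConfig = field(default_factory=PanelConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def snapshot(self) -> str:
        return json.dumps(asdict(self), indent=2, default=repr, sort_keys=True)


def _write_snapshot(config: RunConfig, out_dir: Path, stage: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"config_{stage}.json").write_text(config.snapshot())


def run_simulate(config: RunConfig, out_dir: str | Path) -> Dataset:
    """Stage 1: generate a synthetic panel dataset under ``out_dir``."""
    out = Path(out_dir)
    panel = make_panel(config.panel, seed=config.seed)
    ds = generate_dataset(panel, config.acquisition, seed=config.seed, out_dir=out)
    _write_snapshot(config, out, "simulate")
    logger.info(
        "simulated panel: %d variants (+WT), %d suppressed",
        len(panel.variants), len(ds.suppressed),
    )
    return ds


# ---------------------------------------------------------------- fitting


def _fit_variant_rates(
    per_conc: dict, competition: CompetitionSeries | None
) -> RateFitResult:
    """Reduce one variant's traces and competition series to rate constants.

    Replicate traces at each concentration are averaged before fitting
    (SEs then shrink as 1/sqrt(replicates)); each averaged trace is fitted
    with 1 and 2 phases and the AICc winner kept.  Variants whose traces
    have no resolvable signal are flagged unusable.
    """
    result = RateFitResult()
    concs, lam_fast, lam_fast_se = [], [], []
    slow_concs, lam_slow, lam_slow_se = [], [], []
    n_degenerate = 0
    for conc, reps in sorted(per_conc.items()):
        t = reps[0].time_s
        mean_signal = np.mean([r.signal for r in reps], axis=0)
        fit = fit_trace_auto(Trace(time_s=t, signal=mean_signal,
                                   partner_conc=conc, probe_conc=reps[0].probe_conc))
        if not fit.converged or fit.degenerate:
            n_degenerate += 1
            continue
        concs.append(conc)
        lam_fast.append(fit.rates[0])
        lam_fast_se.append(fit.rate_se[0])
        if fit.n_phases == 2:
            slow_concs.append(conc)
            lam_slow.append(fit.rates[1])
            lam_slow_se.append(fit.rate_se[1])
    if n_degenerate:
        result.flags.append(f"degenerate_traces:{n_degenerate}")
    if len(concs) >= 4:
        try:
            (result.k_ass_fast, result.k_ass_fast_se,
             result.intercept, result.intercept_se) = fit_association_series(
                concs, lam_fast, lam_fast_se)
        except ValueError as exc:
            result.flags.append(f"association_fit_failed:{exc}")
            result.usable = False
    else:
        result.flags.append("too_few_usable_traces")
        result.usable = False
    if len(lam_slow) >= 4:
        (result.k_ass_slow, result.k_ass_slow_se,
         result.slow_slope_pvalue) = summarize_slow_phase(
            slow_concs, lam_slow, lam_slow_se)
    else:
        result.flags.append("slow_phase_unresolved")
    if competition is not None:
        kd, kd_se, cflags = fit_dissociation_asymptote(competition)
        result.k_diss, result.k_diss_se = kd, kd_se
        result.flags.extend(f"competition_{f}" for f in cflags)
        if not math.isfinite(kd):
            result.usable = False
    else:
        result.flags.append("no_competition_data")
        result.usable = False
    return result


def fit_dataset(ds: Dataset) -> list[VariantRecord]:
    """Fit every variant of an in-memory dataset (stage 2 core)."""
    records = []
    for v in ds.panel.all_members():
        rates = _fit_variant_rates(
            ds.traces[v.variant_id], ds.competition.get(v.variant_id)
        )
        equilibrium = fit_anisotropy_isotherm(ds.titrations[v.variant_id])
        if not rates.usable:
            logger.info("variant %s flagged unusable: %s", v.variant_id, rates.flags)
        records.append(
            VariantRecord(
                variant_id=v.variant_id,
                position=v.position,
                region=v.region,
                site_class=v.site_class,
                substitution=v.substitution,
                rates=rates,
                equilibrium=equilibrium,
            )
        )
    return records


_RATE_COLUMNS = [
    "variant_id", "k_ass_fast_M-1s-1", "k_ass_fast_se", "intercept_s-1",
    "intercept_se", "k_ass_slow_s-1", "k_ass_slow_se", "slow_slope_pvalue",
    "k_diss_s-1", "k_diss_se", "kd_equb_M", "kd_equb_se", "r_free", "r_bound",
    "usable", "flags",
]


def records_to_table(records: list[VariantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rt, eq = r.rates, r.equilibrium
        rows.append(
            {
                "variant_id": r.variant_id,
                "k_ass_fast_M-1s-1": rt.k_ass_fast,
                "k_ass_fast_se": rt.k_ass_fast_se,
                "intercept_s-1": rt.intercept,
                "intercept_se": rt.intercept_se,
                "k_ass_slow_s-1": rt.k_ass_slow,
                "k_ass_slow_se": rt.k_ass_slow_se,
                "slow_slope_pvalue": rt.slow_slope_pvalue,
                "k_diss_s-1": rt.k_diss,
                "k_diss_se": rt.k_diss_se,
                "kd_equb_M": eq.kd_equb,
                "kd_equb_se": eq.kd_se,
                "r_free": eq.r_free,
                "r_bound": eq.r_bound,
                "usable": r.usable,
                "flags": ";".join(rt.flags) + (";kd_poorly_determined" if eq.poorly_determined else ""),
            }
        )
    return pd.DataFrame(rows, columns=_RATE_COLUMNS)


def table_to_records(rates: pd.DataFrame, metadata: pd.DataFrame) -> list[VariantRecord]:
    """Rebuild variant records from the rate table plus metadata table."""
    meta = metadata.set_index("variant_id")
    records = []
    for _, row in rates.iterrows():
        vid = row["variant_id"]
        m = meta.loc[vid]
        rfr = RateFitResult(
            k_ass_fast=row["k_ass_fast_M-1s-1"], k_ass_fast_se=row["k_ass_fast_se"],
            intercept=row["intercept_s-1"], intercept_se=row["intercept_se"],
            k_ass_slow=row["k_ass_slow_s-1"], k_ass_slow_se=row["k_ass_slow_se"],
            slow_slope_pvalue=row["slow_slope_pvalue"],
            k_diss=row["k_diss_s-1"], k_diss_se=row["k_diss_se"],
            usable=bool(row["usable"]),
            flags=str(row.get("flags", "")).split(";") if row.get("flags") else [],
        )
        eq = EquilibriumResult(
            kd_equb=row["kd_equb_M"], kd_se=row["kd_equb_se"],
            r_free=row["r_free"], r_bound=row["r_bound"],
            converged=math.isfinite(row["kd_equb_M"]),
            poorly_determined="kd_poorly_determined" in str(row.get("flags", "")),
        )
        records.append(
            VariantRecord(
                variant_id=vid, position=int(m["position"]), region=m["region"],
                site_class=m["site_class"], substitution=m["substitution"],
                rates=rfr, equilibrium=eq,
            )
        )
    return records


def _read_traces_dir(vdir: Path) -> dict:
    per_conc: dict = {}
    for f in sorted(vdir.glob("conc*_rep*.tsv")):
        df, meta = tio.read_table(f)
        conc = float(meta["partner_conc_M"])
        probe = float(meta.get("probe_conc_M", "0") or 0)
        per_conc.setdefault(conc, []).append(
            Trace(time_s=df["time_s"].to_numpy(), signal=df["signal"].to_numpy(),
                  partner_conc=conc, probe_conc=probe)
        )
    return per_conc


def run_fit(data_dir: str | Path, config: RunConfig, out_path: str | Path) -> pd.DataFrame:
    """Stage 2: fit every variant found in a dataset directory.

    Reads the trace/titration/competition files written by stage 1 (or by
    any instrument-export converter producing the same formats), writes the
    per-variant rate/equilibrium table to ``out_path`` and returns it.
    Unusable variants are flagged in the table, never dropped.
    """
    data = Path(data_dir)
    metadata, _ = tio.read_table(data / "metadata.tsv")
    records = []
    for _, m in metadata.iterrows():
        vid = m["variant_id"]
        vdir = data / "traces" / vid
        per_conc = _read_traces_dir(vdir) if vdir.is_dir() else {}
        comp_path = data / "competition" / f"{vid}.tsv"
        competition = None
        if comp_path.exists():
            cdf, _ = tio.read_table(comp_path)
            competition = CompetitionSeries(
                competitor_conc=cdf["competitor_conc_M"].to_numpy(),
                k_obs=cdf["k_obs_s"].to_numpy(),
                k_obs_se=cdf["k_obs_se_s"].to_numpy() if "k_obs_se_s" in cdf else None,
            )
        rates = (
            _fit_variant_rates(per_conc, competition)
            if per_conc
            else RateFitResult(usable=False, flags=["no_trace_data"])
        )
        tit_path = data / "titrations" / f"{vid}.tsv"
        if tit_path.exists():
            tdf, tmeta = tio.read_table(tit_path)
            curve = TitrationCurve(
                probe_conc=float(tmeta["probe_conc_M"]),
                partner_total=tdf["partner_total_M"].to_numpy(),
                anisotropy=tdf["anisotropy"].to_numpy(),
            )
            equilibrium = fit_anisotropy_isotherm(curve)
        else:
            equilibrium = EquilibriumResult(
                kd_equb=math.nan, kd_se=math.nan, r_free=math.nan, r_bound=math.nan,
                converged=False, poorly_determined=True,
            )
        records.append(
            VariantRecord(
                variant_id=vid, position=int(m["position"]), region=m["region"],
                site_class=m["site_class"], substitution=m["substitution"],
                rates=rates, equilibrium=equilibrium,
            )
        )
    table = records_to_table(records)
    out_path = Path(out_path)
    tio.write_table(
        out_path, table,
        {
            "units": "k_ass_fast M^-1 s^-1; k_ass_slow, k_diss, intercept s^-1; kd M",
            "convention": "SEs are 1-sigma from fit covariance",
        },
    )
    _write_snapshot(config, out_path.parent, "fit")
    return table


# ---------------------------------------------------------------- phi stage


def phi_report(
    records: list[VariantRecord], config: RunConfig
) -> dict[str, pd.DataFrame]:
    """Stage 3 core: full phi analysis of fitted variant records.

    Interface and surface-Ala variants are analysed against the wild type;
    the glycine member of each surface pair against its alanine partner
    (composite Ala->Gly step).  Applies the dual-branch ddG filter and the
    branch-consistency exclusion, classifies reportable variants, and
    assembles the phi table, region summary, LFE table and the
    kinetic-vs-equilibrium Kd comparison.

    Raises
    ------
    ValueError
        If there is not exactly one wild-type record.
    """
    wts = [r for r in records if r.is_wild_type]
    if len(wts) != 1:
        raise ValueError(
            f"panel must contain exactly one wild-type record, found {len(wts)}"
        )
    wt = wts[0]
    by_id = {r.variant_id: r for r in records}
    alas_by_pos = {
        r.position: r
        for r in records
        if r.site_class == "surface" and r.substitution == "X->A"
    }

    results: list[PhiResult] = []
    for r in records:
        if r.is_wild_type:
            continue
        if r.substitution == "A->G":
            ala = alas_by_pos.get(r.position)
            if ala is None:
                res = PhiResult(variant_id=r.variant_id, flags=["missing_ala_partner"])
            else:
                res = composite_ala_gly(ala, r, config.temperature)
        else:
            res = phi_for_variant(r, wt, config.temperature)
        results.append(res)

    results = apply_report_filter(results, config.ddg_threshold)
    results = apply_consistency(results, config.consistency_tolerance)
    results = classify_panel(results, config.classification)
    n_reportable = sum(r.reportable for r in results)
    logger.info(
        "phi analysis: %d variants in, %d reportable phi-values, %d consistent",
        len(results), n_reportable, sum(r.consistent for r in results),
    )

    def mcol(m: Measurement | None) -> tuple[float, float]:
        return (m.value, m.se) if m is not None else (math.nan, math.nan)

    rows = []
    mutants = [r for r in records if not r.is_wild_type]
    for rec, res in zip(mutants, results):
        kd_kin_v, kd_kin_se = mcol(res.kd_kin)
        ddg_e, ddg_e_se = mcol(res.ddg_equb)
        ddg_k, ddg_k_se = mcol(res.ddg_kin)
        phi_e, phi_e_se = mcol(res.phi_equb)
        phi_k, phi_k_se = mcol(res.phi_kin)
        phi_a, phi_a_se = mcol(res.phi_average)
        rows.append(
            {
                "variant_id": res.variant_id,
                "region": rec.region,
                "site_class": rec.site_class,
                "substitution": rec.substitution,
                "kd_kin_M": kd_kin_v, "kd_kin_se": kd_kin_se,
                "ddg_equb_kcal_mol": ddg_e, "ddg_equb_se": ddg_e_se,
                "ddg_kin_kcal_mol": ddg_k, "ddg_kin_se": ddg_k_se,
                "phi_equb": phi_e, "phi_equb_se": phi_e_se,
                "phi_kin": phi_k, "phi_kin_se": phi_k_se,
                "phi_average": phi_a, "phi_average_se": phi_a_se,
                "reportable": res.reportable,
                "consistent": res.consistent,
                "ts_class": res.ts_class or "",
                "flags": ";".join(res.flags),
            }
        )
    phi_table = pd.DataFrame(rows)

    usable = [r for r in records if r.usable]
    lfe, slopes = lfe_table(usable)
    lfe_slopes = pd.DataFrame(
        [
            {"rate": k, "slope_vs_log_kd": s, "slope_se": se}
            for k, (s, se) in slopes.items()
        ]
    )
    kd_cmp, frac_cover = compare_kd(usable)
    variant_meta = [r for r in records if not r.is_wild_type]
    region = region_summary(results, variant_meta)
    return {
        "phi": phi_table,
        "region_summary": region,
        "lfe": lfe,
        "lfe_slopes": lfe_slopes,
        "kd_comparison": kd_cmp,
        "summary": pd.DataFrame(
            [
                {
                    "n_variants": len(mutants),
                    "n_reportable": n_reportable,
                    "n_inconsistent": sum(not r.consistent for r in results),
                    "kd_ratio_ci_coverage": frac_cover,
                }
            ]
        ),
    }


_PHI_HEADER = {
    "units": "ddg kcal/mol (destabilizing positive); kd M; phi unitless",
    "convention": (
        "phi = ln(k_ass_ref/k_ass_mut)/ln(Kd_mut/Kd_ref); SEs first-order "
        "delta-method; shared-reference correlation between variants ignored"
    ),
}


def run_phi(
    rates_path: str | Path,
    metadata_path: str | Path,
    config: RunConfig,
    out_dir: str | Path,
) -> dict[str, pd.DataFrame]:
    """Stage 3: phi report from a rate table + metadata table on disk."""
    rates, _ = tio.read_table(rates_path)
    metadata, _ = tio.read_table(metadata_path)
    records = table_to_records(rates, metadata)
    tables = phi_report(records, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        tio.write_table(out / f"{name}.tsv", df, _PHI_HEADER)
    _write_snapshot(config, out, "phi")
    return tables
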