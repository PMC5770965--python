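"""Synthetic mutant-panel generator with carried ground truth.

Emulates the data a FITC-labelled peptide panel produces in a coupled
folding-and-binding study: per-variant association traces (biphasic: a fast
phase linear in partner concentration plus a low-amplitude, concentration-
independent slow phase), equilibrium anisotropy titrations with ligand
depletion, competition-dissociation series, and residual-helicity CD
readouts.  Every generated quantity exists as ground truth in
:class:`PanelTruth`, so each downstream estimator can be tested for
recovery without any external data.

Ground truth is stated in the terms the analysis identifies: a per-variant
binding free-energy change ``ddg_true`` and a transition-state phi-value
``phi_true``.  Microscopic rates are derived by inverting the phi
definition — the association rate scales as ``Kd^(-phi)`` and the residual
destabilization is placed on the dissociation side — with the
isomerization rates held at wild-type values across all variants (the slow
phase is insensitive to mutation).

By default the binding reaction itself is two-state and the slow
association phase is generated as a mutation- and concentration-independent
unimolecular signal component downstream of binding.  This keeps
``Kd_kin = Kd_equb`` exactly, making ground-truth recovery well-posed (see
docs/methods.md for why a literal induced-fit scheme with all
destabilization on the encounter complex cannot reproduce the observed
kinetic/equilibrium agreement over a multi-decade ddG range).  A
three-state wild-type scheme can be supplied instead, in which case the
small systematic Kd_kin/Kd_equb offset of the induced-fit model is a
feature of the generated world.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetic_model import (
    KineticScheme,
    Trace,
    apparent_koff,
    equilibrium_kd,
    simulate_traces,
)
from .equilibrium_binding import (
    HelicityBaselines,
    TitrationCurve,
    fraction_bound,
    mre_from_fraction_helix,
)
from .trace_fitting import CompetitionSeries
from .phi_analysis import GAS_CONSTANT_KCAL
from . import io as tio

__all__ = [
    "VariantTruth",
    "PanelTruth",
    "PanelConfig",
    "AcquisitionConfig",
    "HelicityConfig",
    "Dataset",
    "make_panel",
    "generate_dataset",
    "generate_cd",
]


@dataclass(frozen=True)
class VariantTruth:
    """Ground truth for one panel member.

    ``ddg_true`` is the binding free-energy change versus the wild type
    (kcal/mol, destabilizing positive); ``phi_true`` the transition-state
    phi used to split that change between association and dissociation.
    For the glycine member of a surface Ala/Gly pair the analysis-facing
    perturbation is the composite Ala->Gly step, available as
    ``ddg_composite_true`` (its phi equals ``phi_true`` by construction:
    the whole position shares one phi).
    """

    variant_id: str
    position: int
    region: str
    site_class: str
    substitution: str
    ddg_true: float
    phi_true: float  # nan for wild type
    scheme: KineticScheme
    reference_id: str = "WT"
    ddg_composite_true: float = math.nan  # A->G step, gly variants only

    @property
    def is_wild_type(self) -> bool:
        return self.substitution == "wild-type"


@dataclass
class PanelTruth:
    """The full stated world: every variant's truth plus panel-level settings."""

    wild_type: VariantTruth
    variants: list[VariantTruth]
    temperature: float
    seed: int
    config: "PanelConfig"

    def all_members(self) -> list[VariantTruth]:
        return [self.wild_type, *self.variants]

    def by_id(self, variant_id: str) -> VariantTruth:
        for v in self.all_members():
            if v.variant_id == variant_id:
                return v
        raise KeyError(variant_id)

    def kd_equb_true(self, v: VariantTruth) -> float:
        return equilibrium_kd(v.scheme)

    def kd_kin_true(self, v: VariantTruth) -> float:
        return apparent_koff(v.scheme) / v.scheme.k_on

    def truth_table(self) -> pd.DataFrame:
        """Per-variant truth on the analysis scale (one row per phi row).

        Interface and surface-Ala rows are referenced to the wild type;
        glycine rows to their alanine partner (the composite step).  Both
        branch ddG truths are included so filter counts can be computed on
        exactly the rule the analysis applies.
        """
        rt = GAS_CONSTANT_KCAL * self.temperature
        rows = []
        for v in self.all_members():
            ref = self.by_id(v.reference_id) if not v.is_wild_type else v
            if v.is_wild_type:
                ddg_e = ddg_k = 0.0
                ddg_nominal = 0.0
            else:
                ddg_e = rt * math.log(self.kd_equb_true(v) / self.kd_equb_true(ref))
                ddg_k = rt * math.log(self.kd_kin_true(v) / self.kd_kin_true(ref))
                ddg_nominal = (
                    v.ddg_composite_true if v.substitution == "A->G" else v.ddg_true
                )
            rows.append(
                {
                    "variant_id": v.variant_id,
                    "reference_id": v.reference_id if not v.is_wild_type else "",
                    "position": v.position,
                    "region": v.region,
                    "site_class": v.site_class,
                    "substitution": v.substitution,
                    "ddg_true_kcal_mol": ddg_nominal,
                    "ddg_equb_true_kcal_mol": ddg_e,
                    "ddg_kin_true_kcal_mol": ddg_k,
                    "phi_true": v.phi_true,
                    "k_on_M-1s-1": v.scheme.k_on,
                    "k_off_s-1": v.scheme.k_off,
                    "k_f_s-1": v.scheme.k_f,
                    "k_u_s-1": v.scheme.k_u,
                    "kd_equb_true_M": self.kd_equb_true(v),
                    "kd_kin_true_M": self.kd_kin_true(v),
                }
            )
        return pd.DataFrame(rows)


# Panel layout: positions are synthetic residue indices along a ~28-residue
# helix-kink-helix peptide; the counts (>= 10 interface alanine variants,
# 6 surface Ala/Gly positions, three per helix) mirror the experimental
# design the pipeline targets.
_DEFAULT_INTERFACE = {
    "helix_A": (121, 124, 125, 126),
    "kink": (128, 131, 133),
    "helix_B": (137, 138, 140),
}
_DEFAULT_SURFACE = {
    "helix_A": (119, 122, 123),
    "helix_B": (132, 135, 136),
}


@dataclass
class PanelConfig:
    """Stated-world parameters of the synthetic panel.

    The wild-type scheme defaults to a two-state binding reaction with
    k_on = 1e6 M^-1 s^-1 and k_off = 0.5 s^-1 (Kd = 0.5 uM) — an
    order-of-magnitude fixture typical of peptide-domain interactions, not
    a measured value.  Per-region phi ranges encode the qualitative
    transition-state pattern being emulated: low positive phi in both
    helices (higher toward the C-terminal helix), negative phi in the
    interhelical kink, and all |phi| well below 1.  ddG ranges keep
    reportable variants clear of the 0.34 kcal/mol filter boundary while
    surface Ala steps and N-terminal-helix composites stay below it.
    """

    wild_type_scheme: KineticScheme = field(
        default_factory=lambda: KineticScheme(k_on=1e6, k_off=0.5)
    )
    temperature: float = 298.15
    interface_positions: dict = field(default_factory=lambda: dict(_DEFAULT_INTERFACE))
    surface_positions: dict = field(default_factory=lambda: dict(_DEFAULT_SURFACE))
    # per-region (low, high) ranges for interface X->A variants
    ddg_interface: dict = field(
        default_factory=lambda: {
            "helix_A": (0.5, 1.0),
            "kink": (0.6, 1.5),
            "helix_B": (1.2, 2.6),
        }
    )
    phi_interface: dict = field(
        default_factory=lambda: {
            "helix_A": (0.10, 0.35),
            "kink": (-0.20, -0.05),
            "helix_B": (0.20, 0.40),
        }
    )
    # surface Ala step (vs wild type) and composite Ala->Gly step ranges
    ddg_surface_ala: tuple = (-0.10, 0.20)
    ddg_surface_gly: dict = field(
        default_factory=lambda: {"helix_A": (0.10, 0.30), "helix_B": (0.50, 1.00)}
    )
    phi_surface: dict = field(
        default_factory=lambda: {"helix_A": (0.10, 0.30), "helix_B": (0.10, 0.30)}
    )
    # optional severely destabilized variant whose bound-state signal change
    # is suppressed below detection (no usable association fit)
    include_severe: bool = False
    severe_position: int = 134
    severe_ddg: float = 4.09  # ~3 RT ln 10: a thousand-fold Kd increase
    severe_phi: float = 0.2


def _scheme_for(
    wt: KineticScheme, ddg_vs_wt: float, phi: float, temperature: float
) -> KineticScheme:
    """Invert the phi definition into microscopic rates.

    kd_mut = kd_wt * exp(ddg / RT);
    k_on_mut = k_on_wt * (kd_mut / kd_wt)^(-phi)  (association share);
    k_off_mut then absorbs the residual destabilization so that the
    scheme's equilibrium Kd equals kd_mut, with k_f and k_u held at
    wild-type values.
    """
    rt = GAS_CONSTANT_KCAL * temperature
    kd_wt = equilibrium_kd(wt)
    kd_mut = kd_wt * math.exp(ddg_vs_wt / rt)
    ratio = kd_mut / kd_wt
    k_on = wt.k_on * ratio ** (-phi)
    if wt.is_two_state:
        k_off = kd_mut * k_on
    else:
        k_off = kd_mut * k_on * (1.0 + wt.k_f / wt.k_u)
    if k_on <= 0 or k_off <= 0:
        raise ValueError("ddg/phi combination yields non-positive rates")
    return KineticScheme(k_on=k_on, k_off=k_off, k_f=wt.k_f, k_u=wt.k_u)


def make_panel(config: PanelConfig | None = None, seed: int = 0) -> PanelTruth:
    """Draw a full panel truth from the configured ranges.

    Interface positions receive single X->A variants; each surface position
    receives an Ala and a Gly variant sharing one position, region and phi
    (so the composite Ala->Gly phi is the position's phi exactly).
    Identical seeds give identical panels.
    """
    cfg = config or PanelConfig()
    rng = np.random.default_rng(seed)
    wt = VariantTruth(
        variant_id="WT",
        position=0,
        region="helix_A",
        site_class="interface",
        substitution="wild-type",
        ddg_true=0.0,
        phi_true=math.nan,
        scheme=cfg.wild_type_scheme,
        reference_id="",
    )
    variants: list[VariantTruth] = []
    for region, positions in cfg.interface_positions.items():
        lo_d, hi_d = cfg.ddg_interface[region]
        lo_p, hi_p = cfg.phi_interface[region]
        for pos in positions:
            ddg = float(rng.uniform(lo_d, hi_d))
            phi = float(rng.uniform(lo_p, hi_p))
            variants.append(
                VariantTruth(
                    variant_id=f"I{pos}A",
                    position=pos,
                    region=region,
                    site_class="interface",
                    substitution="X->A",
                    ddg_true=ddg,
                    phi_true=phi,
                    scheme=_scheme_for(cfg.wild_type_scheme, ddg, phi, cfg.temperature),
                )
            )
    for region, positions in cfg.surface_positions.items():
        lo_g, hi_g = cfg.ddg_surface_gly[region]
        lo_p, hi_p = cfg.phi_surface[region]
        for pos in positions:
            ddg_a = float(rng.uniform(*cfg.ddg_surface_ala))
            ddg_step = float(rng.uniform(lo_g, hi_g))
            phi = float(rng.uniform(lo_p, hi_p))
            ala_id, gly_id = f"S{pos}A", f"S{pos}G"
            variants.append(
                VariantTruth(
                    variant_id=ala_id,
                    position=pos,
                    region=region,
                    site_class="surface",
                    substitution="X->A",
                    ddg_true=ddg_a,
                    phi_true=phi,
                    scheme=_scheme_for(cfg.wild_type_scheme, ddg_a, phi, cfg.temperature),
                )
            )
            variants.append(
                VariantTruth(
                    variant_id=gly_id,
                    position=pos,
                    region=region,
                    site_class="surface",
                    substitution="A->G",
                    ddg_true=ddg_a + ddg_step,
                    phi_true=phi,
                    scheme=_scheme_for(
                        cfg.wild_type_scheme, ddg_a + ddg_step, phi, cfg.temperature
                    ),
                    reference_id=ala_id,
                    ddg_composite_true=ddg_step,
                )
            )
    if cfg.include_severe:
        variants.append(
            VariantTruth(
                variant_id=f"I{cfg.severe_position}A",
                position=cfg.severe_position,
                region="helix_B",
                site_class="interface",
                substitution="X->A",
                ddg_true=cfg.severe_ddg,
                phi_true=cfg.severe_phi,
                scheme=_scheme_for(
                    cfg.wild_type_scheme, cfg.severe_ddg, cfg.severe_phi, cfg.temperature
                ),
            )
        )
    return PanelTruth(
        wild_type=wt, variants=variants, temperature=cfg.temperature, seed=seed, config=cfg
    )


@dataclass
class AcquisitionConfig:
    """How the synthetic instrument samples the panel.

    Partner concentrations, time grid and replicate count are fixture
    choices (8 concentrations, 3 replicates) — plausible for a stopped-flow
    titration but not anchored to any particular experiment.  The slow
    association phase is generated as a unimolecular signal component with
    fixed rate ``slow_rate`` and amplitude fraction ``slow_amp_frac`` of
    the binding amplitude, identical across variants and concentrations.
    Trace noise defaults to 2% of the full binding amplitude.
    """

    partner_concs_M: tuple = tuple(2e-6 * (i + 1) for i in range(8))  # 2-16 uM
    probe_conc_M: float = 1e-7
    t_max_s: float = 4.0
    n_time_points: int = 600
    n_replicates: int = 3
    trace_noise_sd: float = 0.02
    trace_offset: float = 0.05
    trace_amplitude: float = 1.0
    slow_rate_s: float = 1.0
    slow_amp_frac: float = 0.15
    # equilibrium titration
    titration_points: int = 14
    titration_span: tuple = (1 / 30.0, 100.0)  # multiples of the variant Kd
    titration_probe_M: float = 5e-8
    anisotropy_free: float = 0.05
    anisotropy_bound: float = 0.25
    anisotropy_noise_sd: float = 0.002
    # competition dissociation
    competition_concs_M: tuple = tuple(
        float(c) for c in np.geomspace(5e-7, 5e-5, 8)
    )
    competition_k_half_M: float = 1e-6
    competition_rel_noise: float = 0.02
    # signal suppression factor applied to severe variants (no usable
    # signal change, as for a mutation whose Kd is too high to populate
    # the bound complex)
    severe_amp_factor: float = 0.01


@dataclass
class Dataset:
    """In-memory synthetic dataset for one panel."""

    panel: PanelTruth
    acquisition: AcquisitionConfig
    seed: int
    traces: dict  # variant_id -> {conc_M -> list[Trace] (replicates)}
    titrations: dict  # variant_id -> TitrationCurve
    competition: dict  # variant_id -> CompetitionSeries
    suppressed: set  # variant_ids generated with suppressed amplitude


def _variant_traces(
    v: VariantTruth,
    acq: AcquisitionConfig,
    rng: np.random.Generator,
    suppressed: bool,
) -> dict:
    """Replicated association traces for one variant.

    Binding relaxation comes from the exact solution of the variant's
    scheme; the concentration-independent slow component (amplitude
    proportional to the bound fraction, rate ``slow_rate``) and Gaussian
    noise are added on top.
    """
    t = np.linspace(0.0, acq.t_max_s, acq.n_time_points)
    amp_scale = acq.severe_amp_factor if suppressed else 1.0
    out: dict = {}
    for conc in acq.partner_concs_M:
        clean = simulate_traces(
            v.scheme,
            [conc],
            t,
            probe_conc=acq.probe_conc_M,
            amplitudes=(1.0, 1.0),
            offset=0.0,
            noise_sd=0.0,
        )[0]
        f_bound = clean.signal  # fraction of probe bound, exact
        f_eq = f_bound[-1]
        signal0 = (
            acq.trace_offset
            + amp_scale
            * acq.trace_amplitude
            * (
                f_bound
                + acq.slow_amp_frac * f_eq * (1.0 - np.exp(-acq.slow_rate_s * t))
            )
        )
        reps = []
        for _ in range(acq.n_replicates):
            noisy = signal0 + rng.normal(0.0, acq.trace_noise_sd, size=t.shape)
            reps.append(
                Trace(time_s=t.copy(), signal=noisy, partner_conc=conc,
                      probe_conc=acq.probe_conc_M)
            )
        out[conc] = reps
    return out


def _variant_titration(
    v: VariantTruth,
    kd: float,
    acq: AcquisitionConfig,
    rng: np.random.Generator,
) -> TitrationCurve:
    lo, hi = acq.titration_span
    grid = np.geomspace(kd * lo, kd * hi, acq.titration_points - 1)
    partner = np.concatenate([[0.0], grid])
    frac = fraction_bound(partner, acq.titration_probe_M, kd)
    r = acq.anisotropy_free + (acq.anisotropy_bound - acq.anisotropy_free) * frac
    r = r + rng.normal(0.0, acq.anisotropy_noise_sd, size=r.shape)
    r = np.clip(r, 0.0, 0.4)
    return TitrationCurve(
        probe_conc=acq.titration_probe_M, partner_total=partner, anisotropy=r
    )


def _variant_competition(
    v: VariantTruth, acq: AcquisitionConfig, rng: np.random.Generator
) -> CompetitionSeries:
    k_diss_true = apparent_koff(v.scheme)
    c = np.asarray(acq.competition_concs_M)
    k_obs = k_diss_true * c / (c + acq.competition_k_half_M)
    se = acq.competition_rel_noise * k_obs
    if acq.competition_rel_noise > 0:
        k_obs = k_obs * (1.0 + rng.normal(0.0, acq.competition_rel_noise, size=c.shape))
    k_obs = np.maximum(k_obs, 1e-12)
    return CompetitionSeries(
        competitor_conc=c, k_obs=k_obs, k_obs_se=se if acq.competition_rel_noise > 0 else None
    )


def generate_dataset(
    panel: PanelTruth,
    acquisition: AcquisitionConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> Dataset:
    """Generate the full file set (or in-memory dataset) for a panel.

    For every panel member: replicated association traces over the
    concentration series, an anisotropy titration spanning the variant's
    Kd, and a competition-dissociation series.  Fully reproducible from the
    seed.  When ``out_dir`` is given, everything is also written as
    delimited text in the formats the fitting stages read, together with
    the variant metadata, the truth table, and a config snapshot.
    """
    acq = acquisition or AcquisitionConfig()
    rng = np.random.default_rng(seed)
    suppressed = {
        v.variant_id
        for v in panel.variants
        if panel.config.include_severe and v.position == panel.config.severe_position
        and v.site_class == "interface"
    }
    traces, titrations, competition = {}, {}, {}
    for v in panel.all_members():
        traces[v.variant_id] = _variant_traces(v, acq, rng, v.variant_id in suppressed)
        titrations[v.variant_id] = _variant_titration(
            v, equilibrium_kd(v.scheme), acq, rng
        )
        competition[v.variant_id] = _variant_competition(v, acq, rng)
    ds = Dataset(
        panel=panel, acquisition=acq, seed=seed,
        traces=traces, titrations=titrations, competition=competition,
        suppressed=suppressed,
    )
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: Dataset, out_dir: str | Path) -> Path:
    """Serialize a dataset as delimited text under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_common = {"units": "time_s: s; concentrations: M", "seed": ds.seed}
    for vid, per_conc in ds.traces.items():
        for i, (conc, reps) in enumerate(sorted(per_conc.items())):
            for j, tr in enumerate(reps):
                tio.write_table(
                    out / "traces" / vid / f"conc{i:02d}_rep{j}.tsv",
                    pd.DataFrame({"time_s": tr.time_s, "signal": tr.signal}),
                    {
                        "variant_id": vid,
                        "partner_conc_M": repr(conc),
                        "probe_conc_M": repr(tr.probe_conc),
                        **meta_common,
                    },
                )
    for vid, curve in ds.titrations.items():
        tio.write_table(
            out / "titrations" / f"{vid}.tsv",
            pd.DataFrame(
                {"partner_total_M": curve.partner_total, "anisotropy": curve.anisotropy}
            ),
            {"variant_id": vid, "probe_conc_M": repr(curve.probe_conc), **meta_common},
        )
    for vid, series in ds.competition.items():
        df = pd.DataFrame(
            {"competitor_conc_M": series.competitor_conc, "k_obs_s": series.k_obs}
        )
        if series.k_obs_se is not None:
            df["k_obs_se_s"] = series.k_obs_se
        tio.write_table(out / "competition" / f"{vid}.tsv", df,
                        {"variant_id": vid, **meta_common})
    meta_rows = [
        {
            "variant_id": v.variant_id,
            "position": v.position,
            "region": v.region,
            "site_class": v.site_class,
            "substitution": v.substitution,
        }
        for v in ds.panel.all_members()
    ]
    tio.write_table(out / "metadata.tsv", pd.DataFrame(meta_rows), meta_common)
    tio.write_table(
        out / "truth.tsv",
        ds.panel.truth_table(),
        {"convention": "ddg destabilizing-positive, kcal/mol", **meta_common},
    )
    snapshot = {
        "panel_seed": ds.panel.seed,
        "dataset_seed": ds.seed,
        "temperature_K": ds.panel.temperature,
        "acquisition": asdict(ds.acquisition),
        "suppressed_variants": sorted(ds.suppressed),
    }
    (out / "config_snapshot.json").write_text(json.dumps(snapshot, indent=2, default=repr))
    return out


@dataclass
class HelicityConfig:
    """Residual-helicity world: wild-type fraction helix and mutation shifts.

    The wild-type unbound peptide carries ~17% residual helix; glycine
    substitutions reduce it by ``delta_gly``, interface alanine
    substitutions by ``delta_interface_ala``, surface alanines leave it
    unchanged.  Values are clipped to [0, 1].
    """

    f_helix_wt: float = 0.17
    delta_gly: float = 0.03
    delta_interface_ala: float = 0.01
    delta_surface_ala: float = 0.0
    n_residues: int = 28
    temperature: float = 298.15
    noise_rel: float = 0.0
    baselines: HelicityBaselines = field(default_factory=HelicityBaselines)


def generate_cd(
    panel: PanelTruth, config: HelicityConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-variant mean residue ellipticity at 222 nm.

    The inverse of the fraction-helix estimator is applied to each
    variant's true helicity under the configured baselines, optionally with
    relative Gaussian noise.  Returns a DataFrame with columns
    variant_id, f_helix_true, mre_222.
    """
    cfg = config or HelicityConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for v in panel.all_members():
        f = cfg.f_helix_wt
        if not v.is_wild_type:
            if v.substitution == "A->G":
                f -= cfg.delta_gly
            elif v.site_class == "interface":
                f -= cfg.delta_interface_ala
            else:
                f -= cfg.delta_surface_ala
        f = min(max(f, 0.0), 1.0)
        mre = mre_from_fraction_helix(f, cfg.n_residues, cfg.temperature, cfg.baselines)
        if cfg.noise_rel > 0:
            mre *= 1.0 + rng.normal(0.0, cfg.noise_rel)
        rows.append({"variant_id": v.variant_id, "f_helix_true": f, "mre_222": mre})
    return pd.DataFrame(rows)
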