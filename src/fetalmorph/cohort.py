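"""Synthetic longitudinal cohorts emulating the study design.

The cohort mirrors a fetal-surgery case-control design: n_mmc operated
fetuses imaged pre (~23+6 weeks) and ~2.4 weeks post surgery, plus
GA-matched "early" (~23 weeks) and "late" (~29 weeks) control fetuses, each
imaged once; early and late controls are pair-matched (pair_id) so the
analysis can form paired per-week rates for controls as well.

Default growth-rate distributions are lognormal, located at the order of
magnitude of published control fetal-brain growth (ventricular rate median
648 mm^3/week, IQR ~371-896); the MMC arm of :func:`EffectConfig.default`
carries an elevated post-surgery ventricular rate (median 3699 mm^3/week)
and regionally elevated folding rates (left temporal, left parietal, right
occipital). :func:`EffectConfig.null` removes every group difference, which
is the configuration used for type-I-error calibration.

Every subject also carries a phantom spec derived from its volumes, so any
row of the table can be materialized as a voxel phantom; the statistical
layer runs on the tabulated metrics (volumes from the generative model plus
measurement noise) without voxelizing all subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .phantom import PhantomSpec

__all__ = ["EffectConfig", "Cohort", "generate_cohort", "spec_from_volumes"]

LOBES = ("LF", "RF", "LT", "RT", "LP", "RP", "LO", "RO")
_REF_GA = 23.0  # weeks; baselines anchored here


@dataclass
class EffectConfig:
    """Generative distributions; (median, log-sigma) for lognormal rates."""

    # baseline volumes at 23 weeks (median mm^3, log-sigma)
    vent_baseline: tuple = (5000.0, 0.20)
    wm_baseline: tuple = (60000.0, 0.12)
    cereb_baseline: tuple = (2500.0, 0.15)
    mmc_vent_baseline_factor: float = 1.6   # pre-op ventriculomegaly

    # growth rates mm^3/week (median, log-sigma)
    vent_rate_control: tuple = (648.0, 0.327)
    vent_rate_mmc: tuple = (3699.0, 0.438)
    wm_rate_control: tuple = (7950.0, 0.30)
    wm_rate_mmc: tuple = (7950.0, 0.30)
    cereb_rate_control: tuple = (755.0, 0.35)
    cereb_rate_mmc: tuple = (755.0, 0.35)

    # shape-index change per week: mean, sd (normal)
    si_rate_control: tuple = (0.012, 0.004)
    si_rate_mmc: tuple = (0.012, 0.004)
    si_rate_mmc_lobe: dict = field(default_factory=lambda: {
        "LT": (0.039, 0.012), "LP": (0.032, 0.008), "RO": (0.027, 0.010)})
    si_baseline: tuple = (-0.05, 0.03)      # mean SI at 23 weeks
    mmc_si_baseline_shift: float = 0.05     # pre-op SI elevated in MMC

    # biometry (mm / degrees): noise sd on construction-derived values
    biometry_noise_mm: float = 0.5
    chl_control: tuple = (-4.0, 1.5)
    chl_mmc_pre: tuple = (6.0, 2.0)
    chl_mmc_post: tuple = (1.0, 2.0)
    cso_control: tuple = (82.0, 4.0)
    cso_mmc_pre: tuple = (62.0, 5.0)
    cso_mmc_post: tuple = (75.0, 5.0)

    measurement_cv: float = 0.02  # multiplicative noise on measured volumes

    @classmethod
    def default(cls) -> "EffectConfig":
        return cls()

    @classmethod
    def null(cls) -> "EffectConfig":
        """No group differences anywhere (type-I-error conditions)."""
        c = cls()
        return dc_replace(
            c,
            mmc_vent_baseline_factor=1.0,
            vent_rate_mmc=c.vent_rate_control,
            wm_rate_mmc=c.wm_rate_control,
            cereb_rate_mmc=c.cereb_rate_control,
            si_rate_mmc=c.si_rate_control,
            si_rate_mmc_lobe={},
            mmc_si_baseline_shift=0.0,
            chl_mmc_pre=c.chl_control, chl_mmc_post=c.chl_control,
            cso_mmc_pre=c.cso_control, cso_mmc_post=c.cso_control,
        )

    def with_ventricular_effect_sd(self, n_sd: float) -> "EffectConfig":
        """Null config plus a location shift of the MMC ventricular rate by
        ``n_sd`` standard deviations of the control rate distribution."""
        base = EffectConfig.null()
        med, sig = base.vent_rate_control
        mean = med * np.exp(sig ** 2 / 2.0)
        sd = mean * np.sqrt(np.expm1(sig ** 2))
        return dc_replace(base, vent_rate_mmc=(med + n_sd * sd, sig))


def _lognormal(rng, median_sigma, size=None):
    median, sigma = median_sigma
    return np.exp(rng.normal(np.log(median), sigma, size=size))


def spec_from_volumes(wm_volume: float, vent_volume: float, cereb_volume: float,
                      fold_amplitude: float, seed: int) -> PhantomSpec:
    """Phantom spec whose base-ellipsoid compartments carry the given
    volumes (axis ratios fixed at 1 : 0.82 : 0.68)."""
    region = wm_volume + vent_volume
    abc = 3.0 * region / (4.0 * np.pi)
    a = (abc / (0.82 * 0.68)) ** (1.0 / 3.0)
    axes = (a, 0.82 * a, 0.68 * a)
    vscale = (vent_volume / region) ** (1.0 / 3.0) if vent_volume > 0 else 0.0
    cr = 3.0 * cereb_volume / (4.0 * np.pi)
    ca = (cr / (0.625 * 0.53)) ** (1.0 / 3.0)
    c_axes = (ca, 0.625 * ca, 0.53 * ca)
    center = (0.0, -0.62 * axes[1], -(axes[2] + fold_amplitude + c_axes[2] + 2.0))
    amp = min(fold_amplitude, 0.45 * axes[2])
    return PhantomSpec(semi_axes=axes, fold_amplitude=amp, fold_frequency=6,
                       ventricle_scale=min(vscale, 0.9 - amp / axes[2]),
                       cerebellum_center=center, cerebellum_semi_axes=c_axes,
                       seed=seed)


@dataclass
class Cohort:
    table: pd.DataFrame         # one row per (subject, timepoint), wide metrics
    demographics: pd.DataFrame  # one row per subject
    subjects: dict              # subject_id -> generative parameters + specs
    config: EffectConfig
    seed: int


def _fold_amp(ga: float) -> float:
    return float(np.clip(0.25 * (ga - 21.0), 0.0, 4.0))


def generate_cohort(n_mmc: int = 12, n_early: int = 12, n_late: int = 12,
                    effect_config: EffectConfig | None = None,
                    seed: int = 0) -> Cohort:
    """Draw a full synthetic cohort table with per-subject phantom specs.

    Control pairs require ``n_early == n_late`` for the paired-rate design.
    """
    if min(n_mmc, n_early, n_late) < 2:
        raise ParameterError("need at least 2 subjects per group")
    if n_early != n_late:
        raise ParameterError("control pairing requires n_early == n_late")
    cfg = effect_config or EffectConfig.default()
    rng = np.random.default_rng(seed)
    rows, demo, subjects = [], [], {}

    def volumes_at(v0, rates, ga):
        # floor keeps early-GA extrapolation of large rate draws physical
        return {k: max(v0[k] + rates[k] * (ga - _REF_GA), 50.0) for k in v0}

    def measure(v):
        return {k: max(val * (1.0 + rng.normal(0.0, cfg.measurement_cv)), 1.0)
                for k, val in v.items()}

    def si_values(ga, base, rates):
        return {lobe: base[lobe] + rates[lobe] * (ga - _REF_GA) for lobe in LOBES}

    def make_row(sid, group, timepoint, ga, vols, si, bio):
        meas = measure(vols)
        row = {"subject_id": sid, "group": group, "timepoint": timepoint,
               "ga_weeks": round(ga, 3),
               "ventricles_volume": meas["vent"],
               "unmyelinated_wm_volume": meas["wm"],
               "cerebellum_volume": meas["cereb"]}
        row.update({f"si_{lobe}": si[lobe] + rng.normal(0.0, 0.005) for lobe in LOBES})
        row.update(bio)
        return row

    def biometrics(group_phase, vols, rng):
        # construction-scale biometry: TCD/VW from compartment size + noise
        cereb_a = (3.0 * vols["cereb"] / (4.0 * np.pi * 0.625 * 0.53)) ** (1 / 3)
        region = vols["wm"] + vols["vent"]
        a = (3.0 * region / (4.0 * np.pi * 0.82 * 0.68)) ** (1 / 3)
        vw_mm = (vols["vent"] / region) ** (1 / 3) * a
        chl_d = {"control": cfg.chl_control, "mmc_pre": cfg.chl_mmc_pre,
                 "mmc_post": cfg.chl_mmc_post}[group_phase]
        cso_d = {"control": cfg.cso_control, "mmc_pre": cfg.cso_mmc_pre,
                 "mmc_post": cfg.cso_mmc_post}[group_phase]
        return {"tcd": 2 * cereb_a + rng.normal(0, cfg.biometry_noise_mm),
                "vw": vw_mm + rng.normal(0, cfg.biometry_noise_mm),
                "chl": rng.normal(*chl_d), "cso": rng.normal(*cso_d)}

    # ---- MMC subjects: paired pre/post -----------------------------------
    for i in range(n_mmc):
        sid = f"mmc{i:02d}"
        ga_pre = float(np.clip(rng.normal(23.857, 1.0), 22.0, 25.0))
        dga = float(np.clip(rng.normal(2.36, 0.5), 1.0, 4.0))
        v0 = {"vent": _lognormal(rng, cfg.vent_baseline) * cfg.mmc_vent_baseline_factor,
              "wm": _lognormal(rng, cfg.wm_baseline),
              "cereb": _lognormal(rng, cfg.cereb_baseline)}
        rates = {"vent": _lognormal(rng, cfg.vent_rate_mmc),
                 "wm": _lognormal(rng, cfg.wm_rate_mmc),
                 "cereb": _lognormal(rng, cfg.cereb_rate_mmc)}
        si0 = {lobe: rng.normal(*cfg.si_baseline) + cfg.mmc_si_baseline_shift
               for lobe in LOBES}
        si_r = {lobe: rng.normal(*cfg.si_rate_mmc_lobe.get(lobe, cfg.si_rate_mmc))
                for lobe in LOBES}
        vols_pre = volumes_at(v0, rates, ga_pre)
        vols_post = volumes_at(v0, rates, ga_pre + dga)
        rows.append(make_row(sid, "mmc", "pre", ga_pre, vols_pre,
                             si_values(ga_pre, si0, si_r),
                             biometrics("mmc_pre", vols_pre, rng)))
        rows.append(make_row(sid, "mmc", "post", ga_pre + dga, vols_post,
                             si_values(ga_pre + dga, si0, si_r),
                             biometrics("mmc_post", vols_post, rng)))
        demo.append({"subject_id": sid, "group": "mmc", "ga_weeks": round(ga_pre, 3)})
        subjects[sid] = {
            "rates": rates, "baselines": v0, "si_rates": si_r,
            "spec_pre": spec_from_volumes(vols_pre["wm"], vols_pre["vent"],
                                          vols_pre["cereb"], _fold_amp(ga_pre),
                                          seed=int(rng.integers(2 ** 31))),
            "spec_post": spec_from_volumes(vols_post["wm"], vols_post["vent"],
                                           vols_post["cereb"], _fold_amp(ga_pre + dga),
                                           seed=int(rng.integers(2 ** 31))),
        }

    # ---- control pairs: early_i and late_i share a growth trajectory -----
    for i in range(n_early):
        ga_e = float(np.clip(rng.normal(23.286, 1.24), 21.0, 25.0))
        ga_l = float(np.clip(rng.normal(28.857, 1.43), 26.0, 30.0))
        v0 = {"vent": _lognormal(rng, cfg.vent_baseline),
              "wm": _lognormal(rng, cfg.wm_baseline),
              "cereb": _lognormal(rng, cfg.cereb_baseline)}
        rates = {"vent": _lognormal(rng, cfg.vent_rate_control),
                 "wm": _lognormal(rng, cfg.wm_rate_control),
                 "cereb": _lognormal(rng, cfg.cereb_rate_control)}
        si0 = {lobe: rng.normal(*cfg.si_baseline) for lobe in LOBES}
        si_r = {lobe: rng.normal(*cfg.si_rate_control) for lobe in LOBES}
        for sid, group, ga, tp in ((f"ce{i:02d}", "control_early", ga_e, "single"),
                                   (f"cl{i:02d}", "control_late", ga_l, "single")):
            vols = volumes_at(v0, rates, ga)
            row = make_row(sid, group, tp, ga, vols, si_values(ga, si0, si_r),
                           biometrics("control", vols, rng))
            row["pair_id"] = i
            rows.append(row)
            demo.append({"subject_id": sid, "group": group, "ga_weeks": round(ga, 3)})
            subjects[sid] = {
                "rates": rates, "baselines": v0, "si_rates": si_r, "pair_id": i,
                "spec": spec_from_volumes(vols["wm"], vols["vent"], vols["cereb"],
                                          _fold_amp(ga), seed=int(rng.integers(2 ** 31))),
            }

    table = pd.DataFrame(rows)
    return Cohort(table=table, demographics=pd.DataFrame(demo),
                  subjects=subjects, config=cfg, seed=seed)
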