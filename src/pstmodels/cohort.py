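"""Synthetic study cohorts: generative stand-in for the unshared patient data.

The generator emulates the study design end to end: Parkinson's disease
(PD) agents tested within-subject in four two-day medication conditions
(ON-ON, ON-OFF, OFF-ON, OFF-OFF) or two single-day conditions (ON, OFF),
plus once-tested healthy-control (HC) agents, on the modified or
original task variant.  Agent parameters are drawn per subject from
truncated normal distributions; medication effects are *injected* as
ON-minus-OFF deltas at three independently switchable points mirroring
the three hypotheses a medication study can test:

* ``alpha_*_on_minus_off`` -- a learning effect (day-1 state shifts the
  learning rates);
* ``beta_on_minus_off``   -- an expression effect (day-2 state shifts the
  choice temperature at test);
* ``rho_on_minus_off``    -- a consolidation effect (day-1 state shifts
  overnight value retention).

With all deltas zero the cohort is a true null: downstream paired tests
should be significant at the nominal rate only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .agents import AgentParams, simulate_session
from .metrics import apply_filter, cohort_metrics
from .model import compare_models, fit_mle
from .stats import (
    bonferroni_alpha,
    paired_t,
    pearson_r,
    rm_anova_2x2,
    wilcoxon_signed_rank,
)
from .tasks import TaskSpec, build_session_schedule, get_variant

EXP1_CONDITIONS = ("ON-ON", "ON-OFF", "OFF-ON", "OFF-OFF")
SINGLE_DAY_CONDITIONS = ("ON", "OFF")


class CohortConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Design and parameter-population configuration of a synthetic cohort.

    Defaults reproduce the two-day 2x2 design: 18 PD patients in four
    counterbalanced within-subject conditions and 18 once-tested HC, on
    the modified task.  ``design`` may be ``"exp1"`` (two-day, four
    conditions, memory blocks), ``"exp2"`` (single-day, ON/OFF, modified)
    or ``"exp3"`` (single-day, ON/OFF, original threshold-gated variant).

    Population means/SDs are truncated-normal; draws outside the
    parameter bounds are resampled.  The base retention mean of 0.775
    with the documented consolidation injection ``rho_on_minus_off=0.35``
    puts the two medication states at rho_ON=0.95 and rho_OFF=0.60.
    """

    design: str = "exp1"
    n_pd: int = 18
    n_hc: int = 18
    alpha_gain_mean: float = 0.35
    alpha_gain_sd: float = 0.15
    alpha_loss_mean: float = 0.30
    alpha_loss_sd: float = 0.15
    beta_mean: float = 3.0
    beta_sd: float = 1.0
    rho_mean: float = 0.775
    rho_sd: float = 0.05
    q0: float = 0.5
    alpha_gain_on_minus_off: float = 0.0
    alpha_loss_on_minus_off: float = 0.0
    beta_on_minus_off: float = 0.0
    rho_on_minus_off: float = 0.0
    feedback_mode: str = "bernoulli"
    novel_reps: int | None = None

    @property
    def variant(self) -> str:
        return "original" if self.design == "exp3" else "modified"

    @property
    def conditions(self) -> tuple[str, ...]:
        if self.design == "exp1":
            return EXP1_CONDITIONS
        if self.design in ("exp2", "exp3"):
            return SINGLE_DAY_CONDITIONS
        raise CohortConfigurationError(f"unknown design {self.design!r}")

    def task_spec(self) -> TaskSpec:
        kwargs = {} if self.novel_reps is None else {"novel_reps": self.novel_reps}
        spec = get_variant(self.variant, **kwargs)
        if self.design == "exp2":
            # modified task without memory blocks or the 24 hr delay
            spec = replace(spec, memory_block_trials=0, two_day=False)
        return spec

    def with_consolidation_effect(self, delta: float = 0.35) -> "CohortConfig":
        """The documented default consolidation injection (rho 0.95 vs 0.60)."""
        return replace(self, rho_on_minus_off=delta)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    """Resample a normal draw until it lands inside [lo, hi]."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _draw_subject_params(cfg: CohortConfig, rng: np.random.Generator,
                         pd_patient: bool) -> AgentParams:
    def split(base: float, delta: float, lo: float, hi: float):
        on = float(np.clip(base + delta / 2, lo, hi))
        off = float(np.clip(base - delta / 2, lo, hi))
        return {"ON": on, "OFF": off}

    ag = _truncnorm(rng, cfg.alpha_gain_mean, cfg.alpha_gain_sd, 0.02, 0.98)
    al = _truncnorm(rng, cfg.alpha_loss_mean, cfg.alpha_loss_sd, 0.02, 0.98)
    beta = _truncnorm(rng, cfg.beta_mean, cfg.beta_sd, 0.5, 20.0)
    rho = _truncnorm(rng, cfg.rho_mean, cfg.rho_sd, 0.0, 1.0)
    if not pd_patient:
        # HC carry no medication state; retention matches the OFF level,
        # matching the observed pattern of HC declining like day-1 OFF.
        hc_rho = float(np.clip(rho - cfg.rho_on_minus_off / 2, 0.0, 1.0))
        return AgentParams(alpha_gain=ag, alpha_loss=al, beta=beta, q0=cfg.q0, rho=hc_rho)
    return AgentParams(
        alpha_gain=split(ag, cfg.alpha_gain_on_minus_off, 0.0, 1.0),
        alpha_loss=split(al, cfg.alpha_loss_on_minus_off, 0.0, 1.0),
        beta=split(beta, cfg.beta_on_minus_off, 0.0, 50.0),
        q0=cfg.q0,
        rho=split(rho, cfg.rho_on_minus_off, 0.0, 1.0),
    )


def _params_row(subject_id: str, group: str, p: AgentParams) -> dict:
    row = {"subject_id": subject_id, "group": group}
    for name in ("alpha_gain", "alpha_loss", "beta", "rho"):
        v = getattr(p, name)
        if isinstance(v, dict):
            row[f"{name}_ON"], row[f"{name}_OFF"] = v["ON"], v["OFF"]
        else:
            row[name] = v
    row["q0"] = p.q0
    return row


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a complete synthetic cohort.

    Returns ``(sessions, truth)``: the long-format trial table of every
    session, and the ground-truth parameter table (kept separate so
    session files never leak the generating parameters).  Condition
    order is counterbalanced across PD subjects with a Latin-square
    rotation, and each condition uses a distinct stimulus version.
    Fully reproducible from ``seed`` via per-subject child streams.
    """
    conditions = config.conditions
    spec = config.task_spec()
    n_versions = 4
    if len(conditions) > n_versions:
        raise CohortConfigurationError("more conditions than stimulus versions")

    root = np.random.SeedSequence(seed)
    subject_seqs = root.spawn(config.n_pd + config.n_hc)
    frames, truth_rows = [], []

    for i in range(config.n_pd):
        sid = f"PD{i + 1:02d}"
        seq = subject_seqs[i]
        rng = np.random.default_rng(seq)
        params = _draw_subject_params(config, rng, pd_patient=True)
        truth_rows.append(_params_row(sid, "PD", params))
        order = [conditions[(j + i) % len(conditions)] for j in range(len(conditions))]
        versions = rng.permutation(n_versions)[: len(conditions)]
        for k, cond in enumerate(order):
            # spawn advances the sequence's child counter, so successive
            # calls yield independent streams per session
            sched_seed, sim_seed = (int(s.generate_state(1)[0] % (2**31))
                                    for s in seq.spawn(2))
            sched = build_session_schedule(spec, sched_seed, config.feedback_mode)
            sess = simulate_session(params, sched, cond, sim_seed, subject_id=sid)
            sess["condition_order"] = k
            sess["stimulus_version"] = int(versions[k])
            frames.append(sess)

    for i in range(config.n_hc):
        sid = f"HC{i + 1:02d}"
        seq = subject_seqs[config.n_pd + i]
        rng = np.random.default_rng(seq)
        params = _draw_subject_params(config, rng, pd_patient=False)
        truth_rows.append(_params_row(sid, "HC", params))
        sched_seed, sim_seed = (int(s.generate_state(1)[0] % (2**31))
                                for s in seq.spawn(2))
        sched = build_session_schedule(spec, sched_seed, config.feedback_mode)
        sess = simulate_session(params, sched, "HC", sim_seed, subject_id=sid)
        sess["condition_order"] = 0
        sess["stimulus_version"] = int(rng.integers(n_versions))
        frames.append(sess)

    sessions = pd.concat(frames, ignore_index=True)
    return sessions, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Full pipeline


def _paired_by_condition(metrics: pd.DataFrame, measure: str,
                         cond_a: str, cond_b: str) -> tuple[np.ndarray, np.ndarray]:
    pv = metrics.pivot_table(index="subject_id", columns="condition",
                             values=measure, aggfunc="first")
    if cond_a not in pv or cond_b not in pv:
        raise KeyError(f"conditions {cond_a}/{cond_b} not present")
    return pv[cond_a].to_numpy(), pv[cond_b].to_numpy()


def _battery_row(name, tr, es=None, alpha=0.05, test_type=""):
    row = {
        "analysis": name,
        "test_type": test_type,
        "statistic_name": tr.statistic_name,
        "statistic": tr.statistic,
        "df": str(tr.df),
        "p": tr.p,
        "n": tr.n,
        "alpha": alpha,
        "significant": bool(tr.p < alpha) if np.isfinite(tr.p) else False,
    }
    if es is not None:
        row.update({"d_z": es.d_z, "d_av": es.d_av, "eta_p2": es.eta_p2})
    return row


@dataclass
class StudyReport:
    """All tables produced by one pipeline run, with a text rendering."""

    config: CohortConfig
    seed: int
    metrics: pd.DataFrame
    battery: pd.DataFrame
    model_comparison: pd.DataFrame | None
    group_means: pd.DataFrame

    def to_text(self) -> str:
        parts = [
            f"Synthetic PST study report (design={self.config.design}, seed={self.seed})",
            "",
            "Group means:",
            self.group_means.to_string(index=False, float_format=lambda v: f"{v:.2f}"),
            "",
            "Statistical battery:",
            self.battery.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        if self.model_comparison is not None:
            parts += ["", "Model comparison (summed over subjects):",
                      self.model_comparison.to_string(index=False,
                                                      float_format=lambda v: f"{v:.2f}")]
        return "\n".join(parts)


def analysis_battery(metrics: pd.DataFrame, design: str) -> pd.DataFrame:
    """Run the full test battery on a cohort metrics table.

    Covers: medication and disease effects on final learning accuracy,
    the 2x2 within-subject ANOVA on memory-change scores plus the four
    Bonferroni-corrected paired comparisons (with Wilcoxon checks),
    learning/novel correlation, and choose-A / avoid-B medication and
    disease tests on unfiltered and filtered data.  Single-day designs
    skip the memory analyses.
    """
    rows = []
    pd_m = metrics[metrics["group"] == "PD"]
    hc_m = metrics[metrics["group"] == "HC"]
    two_day = design == "exp1"
    if two_day:
        day1_on = pd_m[pd_m["condition"].isin(["ON-ON", "ON-OFF"])]
        day1_off = pd_m[pd_m["condition"].isin(["OFF-ON", "OFF-OFF"])]
        on_acc = day1_on.groupby("subject_id")["final_learning_accuracy"].mean()
        off_acc = day1_off.groupby("subject_id")["final_learning_accuracy"].mean()
        tr, es = paired_t(on_acc.to_numpy(), off_acc.reindex(on_acc.index).to_numpy())
        rows.append(_battery_row("learning: medication (day1 ON vs OFF)", tr, es, test_type="paired_t"))
    else:
        tr, es = paired_t(*_paired_by_condition(pd_m, "final_learning_accuracy", "ON", "OFF"))
        rows.append(_battery_row("learning: medication (ON vs OFF)", tr, es, test_type="paired_t"))
    from .stats import independent_t

    tr, es = independent_t(
        pd_m.groupby("subject_id")["final_learning_accuracy"].mean().to_numpy(),
        hc_m["final_learning_accuracy"].to_numpy(),
    )
    rows.append(_battery_row("learning: disease (PD vs HC)", tr, es, test_type="independent_t"))

    for measure in ("win_stay", "lose_shift"):
        tr, es = independent_t(
            pd_m.groupby("subject_id")[measure].mean().to_numpy(),
            hc_m[measure].to_numpy(),
        )
        rows.append(_battery_row(f"wsls: disease on {measure}", tr, es, test_type="independent_t"))

    if two_day:
        for measure in ("mem_diff_30_0", "mem_diff_24_30"):
            pv = pd_m.pivot_table(index="subject_id", columns="condition",
                                  values=measure, aggfunc="first")
            cells = pv[list(EXP1_CONDITIONS)].to_numpy()
            anova = rm_anova_2x2(cells)
            for eff, label in (("A", "day1 medication"), ("B", "day2 medication"),
                               ("AxB", "day1 x day2")):
                tr, es = anova[eff]
                rows.append(_battery_row(f"memory {measure}: RM-ANOVA {label}", tr, es, test_type="rm_anova"))
            alpha4 = bonferroni_alpha(0.05, 4)
            for ca, cb in (("ON-ON", "OFF-ON"), ("ON-OFF", "OFF-OFF")):
                x, y = pv[ca].to_numpy(), pv[cb].to_numpy()
                tr, es = paired_t(x, y)
                rows.append(_battery_row(
                    f"memory {measure}: paired {ca} vs {cb}", tr, es, alpha=alpha4,
                    test_type="paired_t"))
                w = wilcoxon_signed_rank(x, y)
                rows.append(_battery_row(
                    f"memory {measure}: wilcoxon {ca} vs {cb}", w, alpha=alpha4,
                    test_type="wilcoxon"))

    tr = pearson_r(metrics["final_learning_accuracy"], metrics["novel_overall"])
    rows.append(_battery_row("novel: correlation with final learning accuracy", tr, test_type="correlation"))

    for label, table in (("unfiltered", metrics),
                         ("filtered", apply_filter(metrics))):
        tab = table if label == "unfiltered" else table[~table["filtered_out"]]
        pd_t = tab[tab["group"] == "PD"]
        hc_t = tab[tab["group"] == "HC"]
        for measure in ("choose_a", "avoid_b"):
            if two_day:
                pv = pd_t.pivot_table(index="subject_id", columns="condition",
                                      values=measure, aggfunc="first")
                for day, (on_conds, off_conds) in (
                    ("day1", (["ON-ON", "ON-OFF"], ["OFF-ON", "OFF-OFF"])),
                    ("day2", (["ON-ON", "OFF-ON"], ["ON-OFF", "OFF-OFF"])),
                ):
                    on = pv.reindex(columns=on_conds).mean(axis=1)
                    off = pv.reindex(columns=off_conds).mean(axis=1)
                    tr, es = paired_t(on.to_numpy(), off.to_numpy())
                    rows.append(_battery_row(
                        f"novel {measure} ({label}): {day} ON vs OFF", tr, es,
                        test_type="paired_t"))
            else:
                try:
                    x, y = _paired_by_condition(pd_t, measure, "ON", "OFF")
                    tr, es = paired_t(x, y)
                    rows.append(_battery_row(
                        f"novel {measure} ({label}): ON vs OFF", tr, es,
                        test_type="paired_t"))
                except KeyError:
                    pass
            tr, es = independent_t(
                pd_t.groupby("subject_id")[measure].mean().to_numpy(),
                hc_t[measure].to_numpy(),
            )
            rows.append(_battery_row(f"novel {measure} ({label}): PD vs HC", tr, es, test_type="independent_t"))

    return pd.DataFrame(rows)


def fit_cohort_models(
    sessions: pd.DataFrame,
    variants: tuple[str, ...] = ("single", "dual", "dual_by_state"),
    n_restarts: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit each model variant to every PD subject and sum criteria.

    The state-conditional variant needs both medication states, so only
    PD subjects are fitted.  Returns a table with per-variant total NLL,
    AIC and BIC and the count of subjects best fit by each variant.
    """
    pd_sessions = sessions[sessions["group"] == "PD"]
    totals = {v: {"nll": 0.0, "aic": 0.0, "bic": 0.0, "best_count": 0} for v in variants}
    rng = np.random.default_rng(seed)
    for sid, g in pd_sessions.groupby("subject_id", sort=True):
        fits = [
            fit_mle(g, variant=v, n_restarts=n_restarts, seed=int(rng.integers(2**31)))
            for v in variants
        ]
        ranked = compare_models(fits)
        totals[ranked.iloc[0]["variant"]]["best_count"] += 1
        for f in fits:
            totals[f.variant.name]["nll"] += f.nll
            totals[f.variant.name]["aic"] += f.aic
            totals[f.variant.name]["bic"] += f.bic
    out = pd.DataFrame([{"variant": v, **d} for v, d in totals.items()])
    out["delta_aic"] = out["aic"] - out["aic"].min()
    return out.sort_values("aic").reset_index(drop=True)


def run_full_pipeline(
    config: CohortConfig,
    seed: int,
    fit_models: bool = True,
    n_restarts: int = 5,
) -> StudyReport:
    """Generate a cohort and run the complete analysis sequence.

    Learning accuracy tests -> (optional) Q-learning model comparison ->
    memory-difference analyses -> novel-pairs tests -> filtered
    re-analysis.  Deterministic given ``seed``: the same seed yields a
    byte-identical report.
    """
    sessions, _truth = generate_cohort(config, seed)
    metrics = apply_filter(cohort_metrics(sessions))
    battery = analysis_battery(metrics, config.design)
    comparison = None
    if fit_models:
        comparison = fit_cohort_models(sessions, n_restarts=n_restarts, seed=seed)
    value_cols = [c for c in ("final_learning_accuracy", "memory_immediate",
                              "memory_30min", "memory_24hr", "mem_diff_24_30",
                              "choose_a", "avoid_b", "novel_overall")
                  if c in metrics.columns]
    group_means = (
        metrics.groupby(["group", "condition"])[value_cols].mean().round(4).reset_index()
    )
    return StudyReport(
        config=config,
        seed=seed,
        metrics=metrics,
        battery=battery,
        model_comparison=comparison,
        group_means=group_means,
    )
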