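"""Synthetic scan-sampling data with the structure the analysis assumes.

The generator emulates the study design: 20-minute observation sessions of
2-minute instantaneous scans, groups of 4-9 individuals observed over
multiple stable/unstable periods. Per scan, each present individual grooms
with probability inv-logit(b0 + b'x_i + u_i + v_p) — covariate-driven
activity plus individual (u) and period (v) random intercepts — and, when
grooming, directs it at a partner drawn from a per-(individual, period)
preference vector sampled from a symmetric Dirichlet whose concentration
depends on the period's stability. Small concentrations yield lopsided
preference vectors, i.e. concentrated grooming and high DEWD; the default
makes unstable periods more concentrated than stable ones
(alpha_unstable < alpha_stable), the direction the analysis is meant to
detect.

Randomness is stream-split from one master seed (population, composition,
effects/preferences and scan draws use independent substreams), so e.g.
changing the scan count does not perturb the roster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import model_inference
from .grooming_network import build_matrix, measures_table
from .reference_tables import periods_frame
from .study_data import (Individual, ObservationPeriod, ValidationError,
                         count_dyads, read_scans)

#: simulation covariates (indicator coded 1) aligned with the model factors
COVARIATES = ("sex_M", "origin_wild", "phc_without", "arrival_adult")

_COV_TO_FACTOR = {"origin_wild": "Origin", "sex_M": "Sex",
                  "phc_without": "PHCinfant", "arrival_adult":
                  "ArrivalAgeCat"}


def _study_period_plan() -> tuple[tuple[int, str, int], ...]:
    """(group size, stability, n_scans) mirroring the published chronology."""
    frame = periods_frame()
    return tuple(
        (len(str(row["members"]).split(";")), str(row["stability"]), 480)
        for _, row in frame.iterrows())


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults: 18 subjects, the published period plan
    (18 periods, sizes 4-9, 7 stable / 11 unstable) at 480 scans each,
    baseline per-scan grooming probability ~10% (logit intercept -2.2,
    putting VSC near the low-percent range the measures live on), a
    wild-origin deficit of 1 logit on activity, and partner concentration
    alpha 5 (stable) vs 0.8 (unstable)."""

    n_individuals: int = 18
    covariate_probs: dict[str, float] = field(
        default_factory=lambda: {c: 0.5 for c in COVARIATES})
    periods: tuple[tuple[int, str, int], ...] = field(
        default_factory=_study_period_plan)
    beta: dict[str, float] = field(default_factory=lambda: {
        "intercept": -2.2, "origin_wild": -1.0, "sex_M": 0.0,
        "phc_without": 0.0, "arrival_adult": 0.0})
    sigma_id: float = 0.3
    sigma_period: float = 0.2
    alpha_stable: float = 5.0
    alpha_unstable: float = 0.8
    presence_prob: float = 1.0  # per-member per-scan presence probability
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in self.covariate_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"covariate prob {name}={p} not in "
                                      "[0,1]")
        if self.alpha_stable <= 0 or self.alpha_unstable <= 0:
            raise ValidationError("Dirichlet concentrations must be > 0")
        if self.alpha_unstable > self.alpha_stable:
            raise ValidationError(
                "alpha_unstable must not exceed alpha_stable (unstable "
                "periods concentrate grooming)")
        for size, stability, n_scans in self.periods:
            if stability not in ("stable", "unstable"):
                raise ValidationError(f"bad stability {stability!r}")
            if n_scans < 1:
                raise ValidationError("n_scans must be >= 1")
            if size < 2:
                raise ValidationError("group size must be >= 2")
        if not 0.0 < self.presence_prob <= 1.0:
            raise ValidationError("presence_prob must be in (0, 1]")


@dataclass
class SimTruth:
    """Realized latent state: random effects, preferences, coefficients."""

    beta: dict[str, float]
    u_individual: dict[str, float]
    v_period: dict[str, float]
    preferences: dict[str, dict[str, float]]  # "id|period" -> partner->prob

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "beta": self.beta, "u_individual": self.u_individual,
            "v_period": self.v_period, "preferences": self.preferences,
        }, indent=2, sort_keys=True))
        return path


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(stream,)))


def generate_population(cfg: SimConfig) -> list[Individual]:
    """Draw the roster: independent Bernoulli covariates per individual."""
    rng = _rng(cfg, 0)
    roster = []
    for i in range(cfg.n_individuals):
        draw = {c: rng.random() < cfg.covariate_probs.get(c, 0.5)
                for c in COVARIATES}
        roster.append(Individual(
            id=f"C{i + 1:02d}",
            sex="M" if draw["sex_M"] else "F",
            origin="wild" if draw["origin_wild"] else "captive",
            phc_infant=("without_conspecifics" if draw["phc_without"]
                        else "with_conspecifics"),
            arrival_age_cat="adult" if draw["arrival_adult"] else
            "subadult"))
    return roster


def _covariate_row(ind: Individual) -> dict[str, float]:
    return {"sex_M": float(ind.sex == "M"),
            "origin_wild": float(ind.origin == "wild"),
            "phc_without": float(ind.phc_infant == "without_conspecifics"),
            "arrival_adult": float(ind.arrival_age_cat == "adult")}


_SESSION_STARTS = (11 * 60, 16 * 60)  # morning / afternoon, minutes
_SCANS_PER_SESSION = 10  # 20-minute session, one scan every 2 minutes
_PERIOD_DAYS = 180


def generate_scans(cfg: SimConfig, roster: list[Individual]
                   ) -> tuple[pd.DataFrame, list[ObservationPeriod],
                              SimTruth]:
    """Simulate all periods; returns scans (scans.csv dialect), periods, truth."""
    for size, _, _ in cfg.periods:
        if size > len(roster):
            raise ValidationError(
                f"group size {size} exceeds roster size {len(roster)}")
    comp_rng = _rng(cfg, 1)
    eff_rng = _rng(cfg, 2)
    scan_rng = _rng(cfg, 3)

    ids = [ind.id for ind in roster]
    covs = {ind.id: _covariate_row(ind) for ind in roster}
    u = {i: float(eff_rng.normal(0.0, cfg.sigma_id)) for i in ids}

    periods: list[ObservationPeriod] = []
    frames: list[pd.DataFrame] = []
    v: dict[str, float] = {}
    prefs: dict[str, dict[str, float]] = {}
    scan_offset = 0
    epoch = date(2006, 1, 1)
    for p_idx, (size, stability, n_scans) in enumerate(cfg.periods):
        code = f"P{p_idx + 1:02d}"
        members = sorted(comp_rng.choice(ids, size=size, replace=False))
        start = epoch + timedelta(days=p_idx * _PERIOD_DAYS)
        period = ObservationPeriod(
            code=code, group="SIM", members=frozenset(members),
            start_date=start,
            end_date=start + timedelta(days=_PERIOD_DAYS),
            stability=stability)
        periods.append(period)
        v[code] = float(eff_rng.normal(0.0, cfg.sigma_period))
        alpha = (cfg.alpha_stable if stability == "stable"
                 else cfg.alpha_unstable)

        pref_mat = np.empty((size, size - 1))
        for j, member in enumerate(members):
            vec = eff_rng.dirichlet(np.full(size - 1, alpha))
            pref_mat[j] = vec
            partners = [m for m in members if m != member]
            prefs[f"{member}|{code}"] = {
                partner: float(p) for partner, p in zip(partners, vec)}

        eta = np.array([
            cfg.beta.get("intercept", 0.0)
            + sum(cfg.beta.get(c, 0.0) * covs[m][c] for c in COVARIATES)
            + u[m] + v[code]
            for m in members])
        p_groom = 1.0 / (1.0 + np.exp(-eta))

        present = np.ones((n_scans, size), dtype=bool)
        if cfg.presence_prob < 1.0:
            present = scan_rng.random((n_scans, size)) < cfg.presence_prob
            thin = present.sum(axis=1) < 2
            present[thin] = True  # a scan needs at least a dyad
        grooms = (scan_rng.random((n_scans, size)) < p_groom) & present
        recipient = np.full((n_scans, size), "", dtype=object)
        others_idx = [[k for k in range(size) if k != j]
                      for j in range(size)]
        for j, member in enumerate(members):
            rows = np.flatnonzero(grooms[:, j])
            if rows.size == 0:
                continue
            choice = scan_rng.choice(others_idx[j], size=rows.size,
                                     p=pref_mat[j])
            for r, target in zip(rows, choice):
                if present[r, target]:
                    recipient[r, j] = members[target]
                else:
                    grooms[r, j] = False  # partner absent: no event scored

        n_sessions = -(-n_scans // _SCANS_PER_SESSION)
        session_day = np.round(np.linspace(
            0, _PERIOD_DAYS - 1, num=n_sessions)).astype(int)
        timestamps = []
        for s in range(n_scans):
            session = s // _SCANS_PER_SESSION
            minute = (_SESSION_STARTS[session % 2]
                      + 2 * (s % _SCANS_PER_SESSION))
            day = start + timedelta(days=int(session_day[session]))
            timestamps.append(datetime(day.year, day.month, day.day,
                                       minute // 60, minute % 60))

        keep = present.ravel()
        frames.append(pd.DataFrame({
            "scan_id": np.repeat(
                np.arange(scan_offset, scan_offset + n_scans), size)[keep],
            "period_code": code,
            "timestamp": np.repeat(
                np.array([t.isoformat(sep=" ") for t in timestamps]),
                size)[keep],
            "individual": np.tile(np.array(members, dtype=object),
                                  n_scans)[keep],
            "grooming_recipient": recipient.ravel()[keep],
        }))
        scan_offset += n_scans

    scans = pd.concat(frames, ignore_index=True)
    truth = SimTruth(beta=dict(cfg.beta), u_individual=u, v_period=v,
                     preferences=prefs)
    return scans, periods, truth


def write_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit roster.csv, periods.csv, scans.csv and truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    roster = generate_population(cfg)
    scans, periods, truth = generate_scans(cfg, roster)
    paths = {
        "roster": outdir / "roster.csv",
        "periods": outdir / "periods.csv",
        "scans": outdir / "scans.csv",
        "truth": outdir / "truth.json",
    }
    pd.DataFrame([{
        "id": r.id, "sex": r.sex, "origin": r.origin,
        "phc_infant": r.phc_infant, "arrival_age_cat": r.arrival_age_cat}
        for r in roster]).to_csv(paths["roster"], index=False)
    pd.DataFrame([{
        "code": p.code, "group": p.group,
        "start_date": p.start_date.isoformat(),
        "end_date": p.end_date.isoformat(), "stability": p.stability,
        "members": ";".join(sorted(p.members))}
        for p in periods]).to_csv(paths["periods"], index=False)
    scans.to_csv(paths["scans"], index=False)
    truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Full-pipeline parameter recovery
# ---------------------------------------------------------------------------

def measures_from_simulation(cfg: SimConfig) -> pd.DataFrame:
    """Generate one dataset and push it through counting and measures."""
    roster = generate_population(cfg)
    scans_df, periods, _ = generate_scans(cfg, roster)
    records = _scan_records(scans_df, periods)
    matrices = []
    for period in periods:
        period_scans = [s for s in records if s.period_code == period.code]
        dyads = count_dyads(period_scans, period)
        matrices.append(build_matrix(dyads, period,
                                     on_zero_copresence="missing"))
    return measures_table(matrices, roster, periods)


def _scan_records(scans_df: pd.DataFrame, periods):
    import io

    buf = io.StringIO()
    scans_df.to_csv(buf, index=False)
    buf.seek(0)
    return read_scans(buf, periods)


def recovery_experiment(cfg: SimConfig, n_replicates: int,
                        seed: int) -> pd.DataFrame:
    """Run generate -> count -> matrices -> measures -> rank -> average
    per replicate; one row per (replicate, factor).

    Columns report the averaged VSC estimate, its RVI, the generating
    coefficient and whether the estimated sign matches it, plus each
    replicate's mean DEWD in stable and unstable periods.
    """
    if n_replicates < 1:
        raise ValidationError("need at least one replicate")
    sub_seeds = np.random.SeedSequence(seed).generate_state(
        n_replicates) & 0x7FFFFFFF
    rows = []
    for rep, rep_seed in enumerate(sub_seeds):
        rep_cfg = replace(cfg, seed=int(rep_seed))
        measures = measures_from_simulation(rep_cfg)
        specs = model_inference.enumerate_candidates(response="vsc")
        fits = [model_inference.fit_lmm(measures, s) for s in specs]
        ranked = model_inference.rank_models(fits)
        averaged = model_inference.average_conditional(ranked)
        dewd_means = measures.groupby("stability")["dewd"].mean()
        for factor, (col, _) in model_inference.FACTORS.items():
            cov_key = next(
                (c for c, f in _COV_TO_FACTOR.items() if f == factor), None)
            true_beta = cfg.beta.get(cov_key, 0.0) if cov_key else 0.0
            est = (float(averaged.table.loc[factor, "estimate"])
                   if factor in averaged.table.index else np.nan)
            rows.append({
                "replicate": rep, "factor": factor,
                "true_effect": true_beta, "estimate": est,
                "rvi": float(averaged.rvi.loc[factor, "rvi"]),
                "sign_match": (bool(np.sign(est) == np.sign(true_beta))
                               if true_beta != 0 and np.isfinite(est)
                               else None),
                "mean_dewd_stable": float(dewd_means.get("stable", np.nan)),
                "mean_dewd_unstable": float(dewd_means.get("unstable",
                                                           np.nan)),
            })
    return pd.DataFrame(rows)
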