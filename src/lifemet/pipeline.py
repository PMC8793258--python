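"""End-to-end orchestration: simulate (or load) a cohort, score the HLS,
adjust metabolites for fasting time, run the metabolome screen, the
survival models, the kernel-machine selection and the mediation
decomposition, writing delimited-text tables and a JSON run manifest.

Every stochastic stage receives an explicit seed derived from the run
seed; unset required parameters fail loudly rather than defaulting
silently.  Re-running with ``resume=True`` skips stages whose outputs are
current for the same resolved parameter hash.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .additive_hazard import hls_rd
from .kernelmachine import BkmrPriors, McmcControls, ProbitKernelMachine
from .lifestyle import score_cohort
from .mediation import consistency_check, decompose_by_group, mediate_relevant
from .metabolites import MetaboliteMatrix, fasting_adjust, percentile_span
from .regression import CovariateSpec, screen_metabolome, weighted_poisson_rate
from .simulate import generate_cohort, scenario_presets, write_cohort

__all__ = ["RunConfig", "run_all", "exclusion_cascade"]


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run."""

    outdir: str
    preset: str | None = None        # synth preset name, or None to load files
    input_dir: str | None = None     # directory with participants/metabolites/outcomes
    n_participants: int | None = None
    model_id: str = "M2"
    hls_variant: str = "main"
    fdr: float = 0.025
    pip_threshold: float = 0.20
    mcmc_iters: int = 4000
    mcmc_burn: int = 2000
    mcmc_thin: int = 5
    bootstrap_B: int = 500
    seed: int = 0
    run_bkmr: bool = True
    bkmr_max_exposures: int = 20
    resume: bool = False

    def __post_init__(self) -> None:
        if self.preset is None and self.input_dir is None:
            raise ValueError("either a synth preset or an input directory is required")
        if self.seed is None:
            raise ValueError("a run seed must be set explicitly")

    def param_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def exclusion_cascade(
    participants: pd.DataFrame,
    matrix: MetaboliteMatrix | None,
    outcomes: pd.DataFrame | None,
    order: tuple = ("metabolomics", "smoking", "education", "bmi", "amed", "ltpa"),
) -> dict:
    """Sequential listwise exclusions with per-step accounting.

    Cross-sectional set: drop rows with missing metabolomics, then each
    listed lifestyle/covariate column in order.  Prospective set:
    additionally drop prevalent diabetes and participants lost to
    follow-up.  Returns masks and a flow table (step, n_excluded,
    n_remaining).
    """
    n = len(participants)
    keep = np.ones(n, dtype=bool)
    steps = [{"step": "enrolled", "n_excluded": 0, "n_remaining": n}]
    for col in order:
        if col == "metabolomics":
            if matrix is None:
                continue
            missing = matrix.values.isna().any(axis=1).to_numpy()
        elif col in participants.columns:
            missing = participants[col].isna().to_numpy()
        else:
            continue
        newly = keep & missing
        keep &= ~missing
        steps.append(
            {"step": col, "n_excluded": int(newly.sum()), "n_remaining": int(keep.sum())}
        )
    cross_sectional = keep.copy()
    if outcomes is not None:
        for col, label in (
            ("prevalent_diabetes", "prevalent type 2 diabetes"),
            ("lost_to_follow_up", "lost to follow-up"),
        ):
            flag = outcomes[col].to_numpy().astype(bool)
            newly = keep & flag
            keep &= ~flag
            steps.append(
                {"step": label, "n_excluded": int(newly.sum()),
                 "n_remaining": int(keep.sum())}
            )
    return {
        "cross_sectional": cross_sectional,
        "prospective": keep,
        "flow": pd.DataFrame(steps),
    }


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    phash = config.param_hash()
    if config.resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("param_hash") == phash and old.get("completed"):
            return old

    manifest: dict = {
        "version": __version__,
        "param_hash": phash,
        "config": asdict(config),
        "stages": {},
        "completed": False,
    }

    def stage(name):
        t0 = _time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {
                "wall_seconds": round(_time.perf_counter() - t0, 3),
                **info,
            }

        return done

    # --- stage: data ---------------------------------------------------
    done = stage("synth")
    if config.preset is not None:
        overrides = {"seed": config.seed}
        if config.n_participants:
            overrides["n_participants"] = config.n_participants
        cfg = scenario_presets(config.preset, **overrides)
        participants, matrix, outcomes, truth = generate_cohort(cfg)
        paths = write_cohort(out / "synth", participants, matrix, outcomes, truth)
        done(preset=config.preset, n=len(participants), seed=config.seed, paths=paths)
    else:
        indir = Path(config.input_dir)
        participants = pd.read_csv(indir / "participants.csv")
        met_values = pd.read_csv(indir / "metabolites.csv")
        groups = json.loads((indir / "groups.json").read_text())
        matrix = MetaboliteMatrix(values=met_values, groups=groups, allow_missing=True)
        outcomes = pd.read_csv(indir / "outcomes.csv")
        truth = None
        done(input_dir=str(indir), n=len(participants))

    # --- stage: exclusions --------------------------------------------
    done = stage("exclusions")
    casc = exclusion_cascade(participants, matrix, outcomes)
    casc["flow"].to_csv(out / "exclusion_flow.csv", index=False)
    cs, pros = casc["cross_sectional"], casc["prospective"]
    done(n_cross_sectional=int(cs.sum()), n_prospective=int(pros.sum()))

    part_cs = participants.loc[cs].reset_index(drop=True)
    mat_cs = MetaboliteMatrix(
        values=matrix.values.loc[cs].reset_index(drop=True),
        groups=matrix.groups,
        units=matrix.units,
    )

    # --- stage: hls ----------------------------------------------------
    done = stage("hls")
    scored = score_cohort(part_cs, variant=config.hls_variant)
    scored.to_csv(out / "hls.csv", index=False)
    hls = scored["hls_total"].to_numpy()
    done(variant=config.hls_variant, median_hls=float(np.median(hls)))

    # --- stage: metab --------------------------------------------------
    done = stage("metab")
    adj = fasting_adjust(mat_cs, part_cs["fasting_hours"].to_numpy())
    adj.values.to_csv(out / "metabolites_adjusted.csv", index=False)
    done(n_metabolites=len(adj.names))

    # --- stage: screen -------------------------------------------------
    done = stage("screen")
    spec = CovariateSpec(model_id=config.model_id)
    w_cs = part_cs["weight"].to_numpy()
    screen = screen_metabolome(adj, hls, spec, part_cs, w_cs, fdr=config.fdr)
    screen.to_csv(out / "screen.csv", index=False)
    selected = screen.loc[screen["selected"], "metabolite"].tolist()
    done(n_selected=len(selected), fdr=config.fdr)

    # --- prospective analysis set ---------------------------------------
    sub = pros[np.asarray(cs)]
    part_p = part_cs.loc[sub].reset_index(drop=True)
    hls_p = hls[sub]
    adj_p = MetaboliteMatrix(
        values=adj.values.loc[sub].reset_index(drop=True),
        groups=adj.groups,
        fasting_adjusted=True,
        units=adj.units,
    )
    outc_p = outcomes.loc[np.asarray(cs) & np.asarray(pros)].reset_index(drop=True)
    w_p = part_p["weight"].to_numpy()
    time_p = outc_p["follow_up_years"].to_numpy()
    event_p = outc_p["incident_diabetes"].to_numpy()

    # --- stage: survival -------------------------------------------------
    done = stage("survival")
    # survey-weighted incidence rate (no covariates)
    inc = weighted_poisson_rate(
        event_p, time_p, pd.DataFrame({"const": np.ones(len(event_p))}), w_p
    )
    incidence_per_10k = float(np.exp(inc.params["const"]) * 10_000)
    # Poisson RR per HLS point
    X_rr = spec.design(part_p)
    X_rr.insert(1, "hls", hls_p.astype(float))
    rr_fit = weighted_poisson_rate(event_p, time_p, X_rr, w_p)
    rr_sum = rr_fit.summary().loc["hls"]
    # additive-hazards RD per HLS point and by category
    rd_res, rds = hls_rd(time_p, event_p, hls_p, part_p, spec, w_p)
    _, rds_cat = hls_rd(time_p, event_p, hls_p, part_p, spec, w_p, categorical=True)
    hls_table = pd.DataFrame(
        [
            {
                "exposure": r.exposure,
                "rd_per_10k_py": r.rd,
                "ci_lower": r.ci[0],
                "ci_upper": r.ci[1],
                "p": r.p,
            }
            for r in rds + rds_cat
        ]
    )
    hls_table.to_csv(out / "hls_survival.csv", index=False)
    # per-metabolite RR/RD rescaled to the p90-p10 span
    met_rows = []
    for name in selected:
        v = adj_p.values[name].to_numpy()
        try:
            p10, p90 = percentile_span(v, w_p)
        except ValueError:
            continue
        span = p90 - p10
        X_m = spec.design(part_p)
        X_m.insert(1, name, v)
        try:
            rrm = weighted_poisson_rate(event_p, time_p, X_m, w_p)
            res_m, _ = _metab_rd(time_p, event_p, v, name, part_p, spec, w_p)
            rd = res_m.rd_for_exposure(name, span=span)
            ci_rr = rrm.summary().loc[name]
            met_rows.append(
                {
                    "metabolite": name,
                    "group": adj_p.groups[name],
                    "span_p90_p10": span,
                    "rr_span": float(np.exp(ci_rr["coef"] * span)),
                    "rr_ci_lower": float(np.exp(ci_rr["ci_lower"] * span)),
                    "rr_ci_upper": float(np.exp(ci_rr["ci_upper"] * span)),
                    "rd_span_per_10k_py": rd.rd,
                    "rd_ci_lower": rd.ci[0],
                    "rd_ci_upper": rd.ci[1],
                }
            )
        except (np.linalg.LinAlgError, RuntimeError, ValueError):
            continue
    pd.DataFrame(met_rows).to_csv(out / "metabolite_survival.csv", index=False)
    done(
        incidence_per_10k_py=incidence_per_10k,
        rr_per_hls_point=float(rr_sum["rate_ratio"]),
        rd_per_hls_point=float(rds[0].rd),
    )

    # --- stage: bkmr -----------------------------------------------------
    relevant: list = []
    if config.run_bkmr:
        done = stage("bkmr")
        pool = selected if selected else adj_p.names
        pool = pool[: config.bkmr_max_exposures]
        Zmat = adj_p.values[pool]
        Xconf = spec.design(part_p).drop(columns="const")
        model = ProbitKernelMachine(
            event_p,
            Zmat,
            Xconf,
            priors=BkmrPriors(),
            mcmc=McmcControls(
                n_iter=config.mcmc_iters,
                burn_in=config.mcmc_burn,
                thin=config.mcmc_thin,
                seed=config.seed + 1,
            ),
        )
        posterior = model.fit()
        pips = posterior.pips(config.pip_threshold)
        pips.to_csv(out / "pips.csv", index=False)
        posterior.overall_risk(seed=config.seed + 2).to_csv(
            out / "overall_risk.csv", index=False
        )
        relevant = pips.loc[pips["relevant"], "metabolite"].tolist()
        done(n_exposures=len(pool), n_relevant=len(relevant),
             acceptance_rate=posterior.acceptance_rate)

    # --- stage: mediate ---------------------------------------------------
    done = stage("mediate")
    sets = {}
    for group in sorted(set(adj_p.groups.values())):
        members = [m for m in adj_p.group_members(group)]
        if members:
            sets[group] = adj_p.values[members]
    if relevant:
        sets["relevant_metabolites"] = adj_p.values[relevant]
    decomp = decompose_by_group(
        time_p,
        event_p,
        hls_p,
        sets,
        part_p,
        spec,
        w_p,
        B=max(200, config.bootstrap_B),
        seed=config.seed + 3,
        jackknife=False,
    )
    table4 = pd.DataFrame(
        [
            {
                "model": f"reference + {d.label}",
                "rd_per_10k_py": d.rd_adj,
                "rd_reference": d.rd_ref,
                "percent_explained": d.percent_explained,
                "ci_lower": d.ci[0],
                "ci_upper": d.ci[1],
            }
            for d in decomp
        ]
    )
    table4.to_csv(out / "decomposition.csv", index=False)
    report = {}
    if relevant:
        med = mediate_relevant(
            time_p, event_p, hls_p, adj_p.values[relevant], part_p, spec, w_p,
            seed=config.seed + 4,
        )
        pd.DataFrame(
            [
                {
                    "mediator": r.mediator,
                    "alpha": r.alpha,
                    "theta_per_10k": r.theta * 10_000,
                    "nie_per_10k_py": r.nie,
                    "ci_lower": r.ci[0],
                    "ci_upper": r.ci[1],
                    "relative": r.relative,
                }
                for r in med
            ]
        ).to_csv(out / "nie.csv", index=False)
        grp = next(d for d in decomp if d.label == "relevant_metabolites")
        report = consistency_check(med, grp)
        (out / "mediation_report.json").write_text(json.dumps(report, indent=1))
    done(n_sets=len(sets), consistency=report.get("consistent"))

    manifest["completed"] = True
    if truth is not None:
        manifest["truth"] = truth.to_dict()
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _metab_rd(time, event, values, name, cohort, spec, weights):
    from .additive_hazard import AdditiveHazardModel

    X = spec.design(cohort).drop(columns="const")
    X.insert(0, name, np.asarray(values, dtype=float))
    res = AdditiveHazardModel(time, event, X, weights).fit()
    return res, res.rd_for_exposure(name)
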