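"""End-to-end orchestration: simulate → clean → fit → kernels → project → correlate.

Every stage is a pure function of (inputs, config, seed); the run directory
receives each stage's artifacts plus a manifest logging seeds and selected
model structures, so any stage can be re-run from cached upstream outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import census as cs
from . import genetics as gn
from . import kernel as kn
from . import projection as pj
from . import vitals as vt
from .simulate import SimulationParams, simulate_census


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    ``scale`` selects the stochastic-simulation sizes: ``full`` is the
    complete analysis (50,000 λ steps × 5000 bootstraps × 1000
    trajectories), ``desk`` a Monte-Carlo-noisy approximation sized for
    interactive use.
    """

    out_dir: str = "run"
    seed: int = 1
    scale: str = "desk"
    census_path: str | None = None      # None -> simulate synthetic data
    dialect: dict | None = None
    sim_overrides: dict = field(default_factory=dict)
    mesh_points: int = 150
    projection: dict = field(default_factory=dict)
    fixture_only: bool = False
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(**raw)

    def run_sizes(self) -> pj.StochasticRunConfig:
        kw = dict(self.projection)
        kw.setdefault("seed", self.seed)
        if self.scale == "full":
            return pj.StochasticRunConfig(**kw)
        if self.scale == "desk":
            return pj.StochasticRunConfig.desk(**kw)
        raise ValueError(f"unknown scale preset {self.scale!r}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "scale": config.scale, "stages": {}}
    stage = "setup"
    try:
        if config.fixture_only:
            stage = "correlate"
            corr = gn.correlate_all(gn.load_genetics_table(),
                                    gn.load_demography_table(),
                                    gn.load_recensus_table())
            corr.to_csv(out / "correlations.csv", index=False)
            manifest["stages"]["correlate"] = {"rows": len(corr),
                                               "source": "packaged tables"}
            _write_json(out / "manifest.json", manifest)
            return manifest

        # --- data --------------------------------------------------------
        stage = "simulate"
        if config.census_path is None:
            params = SimulationParams(**config.sim_overrides)
            df, truth = simulate_census(params, seed=config.seed)
            cs.write_census(df, out / "census.csv")
            _write_json(out / "truth.json", truth.to_dict())
            n_quadrats = dict(params.n_quadrats)
            manifest["stages"]["simulate"] = {
                "rows": len(df), "populations": list(params.populations)}
        else:
            df = cs.read_census(config.census_path, config.dialect)
            n_quadrats = {}
            manifest["stages"]["simulate"] = {"skipped": True,
                                              "census": config.census_path}

        # --- clean -------------------------------------------------------
        stage = "clean"
        histories = cs.build_histories(df)
        summary = cs.summarize_cohort(histories)
        clean = cs.corrected_table(histories)
        clean.to_csv(out / "census_clean.csv", index=False)
        _write_json(out / "cohort_summary.json", summary.to_dict())
        manifest["stages"]["clean"] = summary.to_dict()

        # --- fit ---------------------------------------------------------
        stage = "fit"
        tables = vt.make_tables(histories)
        populations = sorted(df["population"].unique())
        pop_rates, aicc_rows = {}, []
        fit_dir = out / "fits"
        fit_dir.mkdir(exist_ok=True)
        for pop in populations:
            pr = vt.fit_population_rates(tables, pop)
            pop_rates[pop] = pr
            _write_json(fit_dir / f"{pop}.json", {
                "population": pop,
                "recruit_rate": pr.recruit_rate,
                "recruit_size_mean": pr.recruit_size_mean,
                "recruit_size_sd": pr.recruit_size_sd,
                "intervals": list(pr.intervals),
                "fruit_cap": pr.fruit_cap,
                "flags": list(pr.flags),
                "fits": {k: f.to_dict() for k, f in pr.fits.items()},
            })
            for name, f in pr.fits.items():
                aicc_rows.append({
                    "population": pop, "rate": name, "family": f.family,
                    "chosen": f.structure, "n_obs": f.n_obs,
                    "sigma_year": f.sigma_year,
                    **{f"aicc_{k}": v for k, v in f.aicc_table.items()}})
        pd.DataFrame(aicc_rows).to_csv(out / "aicc_summary.csv", index=False)
        manifest["stages"]["fit"] = {
            pop: {name: f.structure for name, f in pr.fits.items()}
            for pop, pr in pop_rates.items()}

        # --- kernels -----------------------------------------------------
        stage = "kernels"
        max_size = float(np.nanmax(df["diameter_mm"].to_numpy(dtype=float)))
        mesh = kn.build_mesh(max_size, n_points=config.mesh_points)
        mean_lambda = {}
        for pop, pr in pop_rates.items():
            K = kn.build_kernel(pr.rateset(), mesh, population=pop)
            mean_lambda[pop] = K.dominant_eigenvalue()
        manifest["stages"]["kernels"] = {
            "mesh": {"n_points": mesh.n_points, "lower": mesh.lower,
                     "upper": mesh.upper},
            "mean_kernel_lambda": mean_lambda}

        # --- project -----------------------------------------------------
        stage = "project"
        run_cfg = config.run_sizes()
        final_year = int(df["year"].max())
        summaries = {}
        for i, (pop, pr) in enumerate(sorted(pop_rates.items())):
            counts = cs.summarize_cohort(
                [h for h in histories if h.population == pop]).alive_by_year
            n0 = counts.get(final_year, 0)
            rng = np.random.default_rng([int(config.seed) % (2 ** 31), 7, i])
            summaries[pop] = pj.bootstrap_population(pr, mesh, n0, run_cfg, rng)
        _write_json(out / "projection_summary.json",
                    {p: s.to_dict() for p, s in summaries.items()})
        manifest["stages"]["project"] = {
            p: {"lambda_s_median": s.lambda_s_median,
                "pr_ext_mean": s.pr_ext_mean,
                "pred_n_mean": s.pred_n_mean}
            for p, s in summaries.items()}

        # --- correlate ---------------------------------------------------
        stage = "correlate"
        demo = pd.DataFrame([{
            "population": p,
            "lambda_s_median": s.lambda_s_median,
            "pr_ext_mean": s.pr_ext_mean,
            "pred_n2019_mean": s.pred_n_mean,
        } for p, s in summaries.items()])
        genetics = gn.load_genetics_table()
        if set(demo["population"]) & set(genetics["population"]):
            corr = gn.correlate_all(genetics, demo, gn.load_recensus_table())
            corr.to_csv(out / "correlations.csv", index=False)
            manifest["stages"]["correlate"] = {"rows": len(corr)}
        else:
            manifest["stages"]["correlate"] = {
                "skipped": "no populations shared with the genetics table"}

        # --- report ------------------------------------------------------
        stage = "report"
        _write_report(out, manifest, summaries, n_quadrats)
        if config.make_figures:
            _make_figures(out, summaries)
        _write_json(out / "manifest.json", manifest)
        return manifest
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (partial outputs in {out})"
        ) from exc


def _write_report(out: Path, manifest: dict, summaries: dict,
                  n_quadrats: dict) -> None:
    lines = ["# Population viability report", ""]
    lines.append("| population | median λ_S (95% CI) | mean Pr_ext (95% CI) "
                 "| mean predicted N (95% CI) |")
    lines.append("|---|---|---|---|")
    for pop, s in sorted(summaries.items()):
        lam_lo, lam_hi = s.lambda_s_ci
        pe_lo, pe_hi = s.pr_ext_ci
        pn_lo, pn_hi = s.pred_n_ci
        lines.append(
            f"| {pop} | {s.lambda_s_median:.3f} ({lam_lo:.3f}–{lam_hi:.3f}) "
            f"| {s.pr_ext_mean:.3f} ({pe_lo:.3f}–{pe_hi:.3f}) "
            f"| {s.pred_n_mean:.1f} ({pn_lo:.1f}–{pn_hi:.1f}) |")
    if n_quadrats:
        lines.append("")
        lines.append("Predicted densities (m⁻²), predicted N divided by "
                     "1 m² quadrat count:")
        for pop, s in sorted(summaries.items()):
            if pop in n_quadrats:
                lines.append(f"- {pop}: "
                             f"{s.pred_n_mean / n_quadrats[pop]:.3f}")
    (out / "report.md").write_text("\n".join(lines) + "\n")


def _make_figures(out: Path, summaries: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, max(len(summaries), 1),
                             figsize=(3 * len(summaries), 3), squeeze=False)
    for ax, (pop, s) in zip(axes[0], sorted(summaries.items())):
        ax.hist(s.lambda_s_draws, bins=30, color="steelblue")
        ax.axvline(1.0, ls="--", c="k")
        ax.set_title(pop)
        ax.set_xlabel(r"$\lambda_S$")
    fig.tight_layout()
    fig.savefig(out / "lambda_s_distributions.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for pop, s in sorted(summaries.items()):
        if s.median_trajectory is not None:
            ax.plot(s.median_trajectory, label=pop)
    ax.set_xlabel("years since final census")
    ax.set_ylabel("median projected N")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "trajectories.png", dpi=100)
    plt.close(fig)
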