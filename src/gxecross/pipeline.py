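"""End-to-end orchestration: QC -> rGE screen -> exploratory -> confirmatory.

A run is a pure function of (inputs, configuration, seed): identical
configurations produce byte-identical machine-readable outputs.  Inputs
come either from on-disk files or from the synthetic-cohort generator
(exactly one of the two must be configured).
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels

import gxecross
from gxecross.cohort import Cohort
from gxecross.exploratory import fit_cgs_interaction, run_snp_scan
from gxecross.qc import QcThresholds, variant_qc
from gxecross.reparam import (
    Classification,
    ReparamFitResult,
    compare_models,
    fit_cgs_family,
    fit_group_family,
)
from gxecross.rge import screen_panel
from gxecross.simulate import GenParams, SimConfig, gen_cohort

__all__ = ["RunConfig", "RunReport", "run_pipeline", "render_tables"]

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` or the (``phenotypes``, ``genotypes``)
    input paths must be present.
    """

    simulate: SimConfig | None = None
    phenotypes: str | None = None
    genotypes: str | None = None
    snp_info: str | None = None
    alpha_rge: float = 0.05
    alpha_scan: float = 0.05
    alpha_confirm: float = 0.05
    hwe_df: int = 1
    qc_thresholds: QcThresholds = field(default_factory=QcThresholds)
    bonferroni_m: int | None = None
    fixed_c_rule: str = "mean_plus_3sd"
    target_snp: str | None = None
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        has_sim = self.simulate is not None
        has_files = self.phenotypes is not None or self.genotypes is not None
        if has_sim and has_files:
            raise ValueError("config must name either input files or a simulate block, not both")
        if not has_sim and not (self.phenotypes and self.genotypes):
            raise ValueError("config must provide a simulate block or both input paths")
        for name in ("alpha_rge", "alpha_scan", "alpha_confirm"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.hwe_df not in (1, 2):
            raise ValueError("hwe_df must be 1 or 2")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        if sim is not None:
            sim = dict(sim)
            params = sim.pop("params", None)
            if params is not None:
                for key in ("group_slopes", "linear_slopes"):
                    if key in params:
                        params[key] = tuple(params[key])
                sim["params"] = GenParams(**params)
            for key in ("mafs", "snp_ids", "pe_parent_probs"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        thr = d.pop("qc_thresholds", None)
        cfg = cls(simulate=sim, **d)
        if thr is not None:
            cfg.qc_thresholds = QcThresholds(**thr)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunReport:
    """All stage outputs of one pipeline run."""

    config: RunConfig
    cohort: Cohort
    qc: object
    screen: object
    scan: object
    cgs_result: object
    target_snp: str | None
    group_fits: dict[str, ReparamFitResult] | None
    cgs_fits: dict[str, ReparamFitResult]
    classification_group: Classification | None
    classification_cgs: Classification
    summary: dict


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _fit_summary(fit: ReparamFitResult) -> dict:
    return {
        "model_id": fit.model_id,
        "c_hat": fit.c_hat,
        "c_fixed": fit.c_fixed,
        "c_se": fit.c_se,
        "c_ci": list(fit.c_ci) if fit.c_ci else None,
        "params": {k: float(v) for k, v in fit.params.items()},
        "se": {k: float(v) for k, v in fit.bse.items()},
        "r2": fit.r2,
        "rss": fit.rss,
        "aic": fit.aic,
        "bic": fit.bic,
        "df": list(fit.df),
        "identified": fit.identified,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute qc -> screen -> explore -> confirm and assemble the report.

    When ``config.out_dir`` is set, per-stage TSVs, the JSON summary and a
    formatted report are written there.
    """
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        cohort = gen_cohort(sim)
    else:
        from gxecross import io

        snp_meta = io.read_snp_info(config.snp_info) if config.snp_info else None
        cohort = io.read_cohort(config.phenotypes, config.genotypes, snp_meta)

    qc = variant_qc(cohort.dosages, config.qc_thresholds, hwe_df=config.hwe_df)
    passing = qc.passing_snps()
    if not passing:
        raise ValueError("no SNPs pass variant QC")
    if passing != cohort.snp_ids:
        cohort = Cohort(
            ids=cohort.ids, phenotype=cohort.phenotype, pe=cohort.pe,
            age=cohort.age, sex=cohort.sex, dosages=cohort.dosages[passing],
            pe_father=cohort.pe_father, pe_mother=cohort.pe_mother, meta=cohort.meta,
        )

    screen = screen_panel(cohort, alpha=config.alpha_rge)
    scan = run_snp_scan(
        cohort, screen.retained, alpha=config.alpha_scan, m_override=config.bonferroni_m
    )
    cgs_result = fit_cgs_interaction(cohort, cgs=screen.cgs_retained)

    target = config.target_snp
    if target is None:
        target = str(scan.table["p"].idxmin())
    group_fits = classification_group = None
    gate_group = False
    if target in scan.fits:
        gate_group = bool(scan.fits[target][2].f > 1.0)
        group_fits = fit_group_family(cohort, target, config.fixed_c_rule)
        classification_group = compare_models(
            group_fits, gate_group, cohort.pe_range(), alpha=config.alpha_confirm
        )
    cgs_fits = fit_cgs_family(cohort, cgs=screen.cgs_retained, fixed_c_rule=config.fixed_c_rule)
    classification_cgs = compare_models(
        cgs_fits, cgs_result.gate_passed, cohort.pe_range(), alpha=config.alpha_confirm
    )

    summary = _jsonify(
        {
            "schema_version": SUMMARY_SCHEMA_VERSION,
            "seed": config.seed,
            "n": cohort.n,
            "versions": {
                "gxecross": gxecross.__version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "statsmodels": statsmodels.__version__,
                "python": platform.python_version(),
            },
            "qc": {"passing_snps": passing},
            "rge": {
                "retained": screen.retained,
                "excluded": [r.label for r in screen.results if r.excluded],
            },
            "scan": {
                "m": scan.m,
                "threshold": scan.threshold,
                "significant": scan.significant,
                "target_snp": target,
            },
            "cgs_gate": {
                "f": cgs_result.comparison.f,
                "p": cgs_result.comparison.p,
                "passed": cgs_result.gate_passed,
            },
            "group_models": {k: _fit_summary(v) for k, v in (group_fits or {}).items()},
            "cgs_models": {k: _fit_summary(v) for k, v in cgs_fits.items()},
            "classification_group": classification_group,
            "classification_cgs": classification_cgs,
        }
    )

    report = RunReport(
        config=config, cohort=cohort, qc=qc, screen=screen, scan=scan,
        cgs_result=cgs_result, target_snp=target, group_fits=group_fits,
        cgs_fits=cgs_fits, classification_group=classification_group,
        classification_cgs=classification_cgs, summary=summary,
    )
    if config.out_dir is not None:
        _write_outputs(report, Path(config.out_dir))
    return report


def _reparam_long_table(fits: dict[str, ReparamFitResult]) -> pd.DataFrame:
    rows = []
    for mid in sorted(fits):
        f = fits[mid]
        rows.append(dict(model_id=mid, quantity="C", estimate=f.c_hat,
                         se=f.c_se if not f.c_fixed else np.nan))
        for name in f.params.index:
            rows.append(dict(model_id=mid, quantity=name,
                             estimate=float(f.params[name]), se=float(f.bse[name])))
        for q, v in (("r2", f.r2), ("rss", f.rss), ("aic", f.aic), ("bic", f.bic),
                     ("df_model", f.df[0]), ("df_resid", f.df[1])):
            rows.append(dict(model_id=mid, quantity=q, estimate=v, se=np.nan))
    return pd.DataFrame(rows)


def _write_outputs(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.qc.per_snp.to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
    report.screen.to_frame().to_csv(out_dir / "rge_screen.tsv", sep="\t", index=False)
    report.scan.table.to_csv(out_dir / "exploratory_scan.tsv", sep="\t", index=False)
    if report.group_fits:
        _reparam_long_table(report.group_fits).to_csv(
            out_dir / "reparam_group.tsv", sep="\t", index=False
        )
    _reparam_long_table(report.cgs_fits).to_csv(
        out_dir / "reparam_cgs.tsv", sep="\t", index=False
    )
    (out_dir / "summary.json").write_text(
        json.dumps(report.summary, indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "report.txt").write_text(render_tables(report))


# ---------------------------------------------------------------------------
# formatted report


def _cell(est, se, fixed=False) -> str:
    if est is None or (isinstance(est, float) and not np.isfinite(est)):
        return "--"
    if fixed or se is None:
        return f"{est:.2f} (--)"
    return f"{est:.2f} ({se:.2f})"


def _model_block(fits: dict[str, ReparamFitResult], order: list[str]) -> str:
    order = [m for m in order if m in fits]
    if not order:
        return ""
    canonical = ["a0", "slope0", "slope1", "slope2", "a1", "a2", "age", "sex"]
    seen = {p_ for m in order for p_ in fits[m].params.index}
    param_names = [p_ for p_ in canonical if p_ in seen]
    param_names += sorted(seen - set(param_names))
    width = 16
    lines = ["Parameter".ljust(10) + "".join(m.ljust(width) for m in order)]
    row = "C".ljust(10)
    for m in order:
        f = fits[m]
        row += _cell(f.c_hat, f.c_se, fixed=f.c_fixed).ljust(width)
    lines.append(row)
    for p_ in param_names:
        row = p_.ljust(10)
        for m in order:
            f = fits[m]
            if p_ in f.params.index:
                row += _cell(float(f.params[p_]), float(f.bse[p_])).ljust(width)
            else:
                row += "--".ljust(width)
        lines.append(row)
    for q in ("r2", "aic", "bic"):
        row = q.upper().ljust(10) if q != "r2" else "R2".ljust(10)
        for m in order:
            v = getattr(fits[m], q if q != "r2" else "r2")
            row += (f"{v:.4f}" if q == "r2" else f"{v:.2f}").ljust(width)
        lines.append(row)
    return "\n".join(lines)


def render_tables(report: RunReport) -> str:
    """Human-readable report mirroring the published two-panel layout."""
    parts = []
    if report.target_snp and report.target_snp in report.scan.fits:
        m1, m2, comp = report.scan.fits[report.target_snp]
        parts.append(f"Standard parameterization - {report.target_snp}")
        width = 16
        lines = ["Parameter".ljust(10) + "Model 1".ljust(width) + "Model 2".ljust(width)]
        names = list(m2.params.index)
        for p_ in names:
            row = p_.ljust(10)
            for fit in (m1, m2):
                if p_ in fit.params.index:
                    row += _cell(float(fit.params[p_]), float(fit.bse[p_])).ljust(width)
                else:
                    row += "--".ljust(width)
            lines.append(row)
        lines.append("R2".ljust(10) + f"{m1.r2:.4f}".ljust(width) + f"{m2.r2:.4f}".ljust(width))
        lines.append(
            "F vs 1".ljust(10) + "--".ljust(width)
            + f"{comp.f:.2f} (p={comp.p:.4f})".ljust(width)
        )
        parts.append("\n".join(lines))
    if report.group_fits:
        parts.append(f"Re-parameterized crossover models - {report.target_snp}")
        parts.append(_model_block(report.group_fits, ["3a", "3b", "3c", "3d"]))
        cls = report.classification_group
        if cls is not None:
            if cls.selected_model is None:
                parts.append(f"Group verdict: {cls.family} (gate_passed={cls.gate_passed})")
            else:
                parts.append(
                    f"Group verdict: {cls.selected_model} -> {cls.family} "
                    f"({cls.strength}, {cls.shape})"
                )
    elif report.classification_group is None and report.target_snp:
        parts.append(
            "Confirmatory stage not run for the target SNP "
            "(no exploratory fit available)."
        )
    parts.append("Re-parameterized crossover models - CGS")
    parts.append(_model_block(report.cgs_fits, ["3e", "3f"]))
    cls = report.classification_cgs
    if not cls.gate_passed:
        parts.append(
            "CGS verdict: confirmatory stage skipped - exploratory interaction "
            "F ratio did not exceed 1.0."
        )
    elif cls.selected_model is None:
        parts.append(f"CGS verdict: {cls.family}")
    else:
        parts.append(f"CGS verdict: {cls.selected_model} -> {cls.family} ({cls.shape})")
    return "\n\n".join(parts) + "\n"
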