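"""Forward and reverse MR orchestration across exposure-outcome pairs.

Reads a YAML run configuration, executes the full stage chain per pair
(p-value filter -> confounder exclusion -> LD clump -> F screen ->
harmonization -> IVW / MR-Egger / weighted median -> Q, Egger intercept,
leave-one-out, residual-sum outlier test), collects per-pair reports with
per-pair error isolation, and exports report tables with "/" sentinels for
methods that are not estimable at the available instrument count.

Reverse mode swaps exposure and outcome roles for flagged pairs and reruns
the identical code path with the reverse instrument p-value threshold.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .estimators import (
    MODEL_RANDOM,
    EggerFit,
    MREstimate,
    ivw,
    mr_egger,
    weighted_median,
)
from .exceptions import ConfigurationError, DegenerateDesignError, NotEstimableError, TsmrError
from .harmonize import (
    DEFAULT_PALINDROME_EAF_LIMIT,
    HarmonizedInstrument,
    harmonize_pair,
    surviving,
    write_harmonization_audit,
)
from .instruments import (
    DEFAULT_CLUMP_WINDOW_KB,
    DEFAULT_F_THRESHOLD,
    DEFAULT_IV_PVAL,
    DEFAULT_LD_R2,
    LDMatrix,
    exclude_snps,
    filter_by_pvalue,
    ld_clump,
    read_exclusion_list,
    read_ld_matrix,
    screen_weak_instruments,
)
from .sensitivity import (
    HeterogeneityResult,
    LeaveOneOutSeries,
    PleiotropyTest,
    PressoResult,
    cochran_q,
    egger_intercept_test,
    leave_one_out,
    mr_presso,
)
from .summary_stats import AssociationTable, StudyMeta, read_association_table

__all__ = [
    "DatasetSpec",
    "RunConfig",
    "MRReport",
    "load_config",
    "run_pair",
    "run_forward",
    "run_reverse",
    "export_reports",
]

logger = logging.getLogger(__name__)

NOT_ESTIMABLE_SENTINEL = "/"

SIGNIFICANCE_ALPHA = 0.05  # raw IVW p < 0.05 flags a pair as significant


@dataclass(frozen=True)
class DatasetSpec:
    """One input GWAS: name, file path, optional column map, study metadata."""

    name: str
    path: str
    meta: StudyMeta
    column_map: Optional[dict[str, str]] = None

    def load(self) -> AssociationTable:
        return read_association_table(self.path, meta=self.meta, column_map=self.column_map)


@dataclass
class RunConfig:
    """Every tunable of a run, with the raw mapping kept for the manifest."""

    seed: int
    output_dir: str
    exposures: list[DatasetSpec]
    outcomes: list[DatasetSpec]
    iv_pval: float = DEFAULT_IV_PVAL
    reverse_iv_pval: float = DEFAULT_IV_PVAL
    ld_r2: float = DEFAULT_LD_R2
    clump_window_kb: float = DEFAULT_CLUMP_WINDOW_KB
    f_threshold: float = DEFAULT_F_THRESHOLD
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT
    drop_palindromic: bool = False
    ivw_model: str = MODEL_RANDOM
    n_boot: int = 1000
    presso_n_sim: int = 1000
    outlier_alpha: float = 0.05
    ld_matrix_path: Optional[str] = None
    exclusion_list_path: Optional[str] = None
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value, low, high in (
            ("iv_pval", self.iv_pval, 0.0, 1.0),
            ("reverse_iv_pval", self.reverse_iv_pval, 0.0, 1.0),
            ("ld_r2", self.ld_r2, 0.0, 1.0),
            ("palindrome_eaf_limit", self.palindrome_eaf_limit, 0.0, 0.5),
            ("outlier_alpha", self.outlier_alpha, 0.0, 1.0),
        ):
            if not (low < value <= high):
                raise ConfigurationError(f"{name} = {value} outside ({low}, {high}]")
        if self.f_threshold < 0:
            raise ConfigurationError("f_threshold must be >= 0")


def _meta_from_dict(name: str, d: dict) -> StudyMeta:
    return StudyMeta(
        trait_name=d.get("trait_name", name),
        trait_type=d["trait_type"],
        n_total=int(d["n_total"]),
        n_cases=None if d.get("n_cases") is None else int(d["n_cases"]),
        n_controls=None if d.get("n_controls") is None else int(d["n_controls"]),
    )


def _dataset_specs(entries: list[dict], base: Path) -> list[DatasetSpec]:
    specs = []
    for e in entries:
        path = Path(e["path"])
        if not path.is_absolute():
            path = base / path
        specs.append(
            DatasetSpec(
                name=e["name"],
                path=str(path),
                meta=_meta_from_dict(e["name"], e["meta"]),
                column_map=e.get("column_map"),
            )
        )
    return specs


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; relative paths resolve against it."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    base = path.parent
    thresholds = raw.get("thresholds", {}) or {}
    est = raw.get("estimators", {}) or {}
    harm = raw.get("harmonize", {}) or {}

    def resolve(key: str) -> Optional[str]:
        value = raw.get(key)
        if value is None:
            return None
        p = Path(value)
        return str(p if p.is_absolute() else base / p)

    return RunConfig(
        seed=int(raw["seed"]),
        output_dir=str(raw.get("output_dir", "out")),
        exposures=_dataset_specs(raw.get("exposures", []), base),
        outcomes=_dataset_specs(raw.get("outcomes", []), base),
        iv_pval=float(thresholds.get("iv_pval", DEFAULT_IV_PVAL)),
        reverse_iv_pval=float(thresholds.get("reverse_iv_pval", DEFAULT_IV_PVAL)),
        ld_r2=float(thresholds.get("ld_r2", DEFAULT_LD_R2)),
        clump_window_kb=float(thresholds.get("clump_window_kb", DEFAULT_CLUMP_WINDOW_KB)),
        f_threshold=float(thresholds.get("f_threshold", DEFAULT_F_THRESHOLD)),
        palindrome_eaf_limit=float(
            thresholds.get("palindrome_eaf_limit", DEFAULT_PALINDROME_EAF_LIMIT)
        ),
        drop_palindromic=bool(harm.get("drop_palindromic", False)),
        ivw_model=str(est.get("ivw_model", MODEL_RANDOM)),
        n_boot=int(est.get("n_boot", 1000)),
        presso_n_sim=int(est.get("presso_n_sim", 1000)),
        outlier_alpha=float(est.get("outlier_alpha", 0.05)),
        ld_matrix_path=resolve("ld_matrix"),
        exclusion_list_path=resolve("exclusion_list"),
        raw=raw,
    )


@dataclass
class MRReport:
    """Everything computed for one exposure-outcome pair."""

    exposure_name: str
    outcome_name: str
    direction: str  # "forward" | "reverse"
    stage_counts: dict[str, int] = field(default_factory=dict)
    harmonized: list[HarmonizedInstrument] = field(default_factory=list)
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    not_estimable: dict[str, str] = field(default_factory=dict)
    egger_fit: Optional[EggerFit] = None
    heterogeneity: dict[str, HeterogeneityResult] = field(default_factory=dict)
    pleiotropy: Optional[PleiotropyTest] = None
    loo: Optional[LeaveOneOutSeries] = None
    presso: Optional[PressoResult] = None
    significant: bool = False
    error: Optional[str] = None

    @property
    def pair_label(self) -> str:
        return f"{self.exposure_name}__{self.outcome_name}__{self.direction}"


def _pair_seed(base_seed: int, exposure: str, outcome: str, direction: str) -> int:
    """Deterministic per-pair seed derived from the run seed and pair identity."""
    digest = 0
    for ch in f"{exposure}|{outcome}|{direction}":
        digest = (digest * 131 + ord(ch)) % (2**31 - 1)
    return int(np.random.SeedSequence((base_seed, digest)).generate_state(1)[0])


def run_pair(
    exposure: AssociationTable,
    outcome: AssociationTable,
    exposure_name: str,
    outcome_name: str,
    cfg: RunConfig,
    ld: Optional[LDMatrix] = None,
    exclusions: Optional[dict[str, str]] = None,
    direction: str = "forward",
    iv_pval: Optional[float] = None,
) -> MRReport:
    """Run the complete stage chain for one pair; errors are captured on the
    report rather than raised (per-pair isolation)."""
    report = MRReport(exposure_name=exposure_name, outcome_name=outcome_name, direction=direction)
    seed = _pair_seed(cfg.seed, exposure_name, outcome_name, direction)
    try:
        report.stage_counts["candidates"] = len(exposure)
        table = filter_by_pvalue(exposure, iv_pval if iv_pval is not None else cfg.iv_pval)
        report.stage_counts["pvalue_filter"] = len(table)
        if exclusions:
            table = exclude_snps(table, exclusions.keys(), reason="confounder-associated")
        report.stage_counts["exclusion"] = len(table)
        if ld is not None:
            clumpable = [r.snp_id for r in table.records if r.snp_id in ld]
            if len(clumpable) < len(table):
                logger.warning(
                    "%s: %d candidate(s) absent from LD matrix kept unclumped",
                    report.pair_label, len(table) - len(clumpable),
                )
            table = ld_clump(table.subset(clumpable), ld, r2_threshold=cfg.ld_r2,
                             window_kb=cfg.clump_window_kb)
        report.stage_counts["ld_clump"] = len(table)
        table, _diags = screen_weak_instruments(table, f_threshold=cfg.f_threshold)
        report.stage_counts["f_screen"] = len(table)

        report.harmonized = harmonize_pair(
            table, outcome,
            palindrome_eaf_limit=cfg.palindrome_eaf_limit,
            drop_palindromic=cfg.drop_palindromic,
        )
        insts = surviving(report.harmonized)
        report.stage_counts["harmonized"] = len(insts)

        _estimate_all(report, insts, cfg, seed)
    except TsmrError as exc:
        report.error = f"{type(exc).__name__}: {exc}"
        logger.error("pair %s failed: %s", report.pair_label, report.error)
    return report


def _estimate_all(
    report: MRReport, insts: list[HarmonizedInstrument], cfg: RunConfig, seed: int
) -> None:
    def attempt(method: str, fn):
        try:
            return fn()
        except (NotEstimableError, DegenerateDesignError) as exc:
            report.not_estimable[method] = str(exc)
            return None

    est_ivw = attempt("IVW", lambda: ivw(insts, model=cfg.ivw_model))
    if est_ivw is not None:
        report.estimates["IVW"] = est_ivw
        report.significant = est_ivw.pval < SIGNIFICANCE_ALPHA

    egger = attempt("MR-Egger", lambda: mr_egger(insts))
    if egger is not None:
        report.estimates["MR-Egger"], report.egger_fit = egger

    wme = attempt("WME", lambda: weighted_median(insts, n_boot=cfg.n_boot, seed=seed))
    if wme is not None:
        report.estimates["WME"] = wme

    if est_ivw is not None and len(insts) >= 2:
        report.heterogeneity["IVW"] = cochran_q(insts, est_ivw)
    if report.egger_fit is not None:
        report.heterogeneity["MR-Egger"] = cochran_q(insts, report.egger_fit)
        report.pleiotropy = egger_intercept_test(report.egger_fit)

    loo = attempt("leave_one_out", lambda: leave_one_out(insts, model=cfg.ivw_model))
    if loo is not None:
        report.loo = loo
    presso = attempt(
        "MR-PRESSO",
        lambda: mr_presso(
            insts, n_sim=cfg.presso_n_sim, outlier_alpha=cfg.outlier_alpha,
            seed=seed, model=cfg.ivw_model,
        ),
    )
    if presso is not None:
        report.presso = presso


def _load_shared(cfg: RunConfig) -> tuple[Optional[LDMatrix], Optional[dict[str, str]]]:
    ld = read_ld_matrix(cfg.ld_matrix_path) if cfg.ld_matrix_path else None
    exclusions = (
        read_exclusion_list(cfg.exclusion_list_path) if cfg.exclusion_list_path else None
    )
    return ld, exclusions


def run_forward(cfg: RunConfig) -> list[MRReport]:
    """Run every exposure x outcome pair in the forward direction."""
    ld, exclusions = _load_shared(cfg)
    exposure_tables = {spec.name: spec.load() for spec in cfg.exposures}
    outcome_tables = {spec.name: spec.load() for spec in cfg.outcomes}
    reports = []
    for exp_spec in cfg.exposures:
        for out_spec in cfg.outcomes:
            reports.append(
                run_pair(
                    exposure_tables[exp_spec.name],
                    outcome_tables[out_spec.name],
                    exp_spec.name,
                    out_spec.name,
                    cfg,
                    ld=ld,
                    exclusions=exclusions,
                    direction="forward",
                    iv_pval=cfg.iv_pval,
                )
            )
    return reports


def run_reverse(
    cfg: RunConfig, significant_pairs: Sequence[tuple[str, str]]
) -> list[MRReport]:
    """Swap roles for each flagged (exposure_name, outcome_name) pair and
    rerun the identical chain with the reverse instrument threshold."""
    if not significant_pairs:
        return []
    ld, exclusions = _load_shared(cfg)
    exposures = {spec.name: spec for spec in cfg.exposures}
    outcomes = {spec.name: spec for spec in cfg.outcomes}
    reports = []
    for exp_name, out_name in significant_pairs:
        if exp_name not in exposures or out_name not in outcomes:
            raise ConfigurationError(f"unknown pair ({exp_name}, {out_name})")
        reports.append(
            run_pair(
                outcomes[out_name].load(),      # disease now supplies instruments
                exposures[exp_name].load(),
                out_name,
                exp_name,
                cfg,
                ld=ld,
                exclusions=exclusions,
                direction="reverse",
                iv_pval=cfg.reverse_iv_pval,
            )
        )
    return reports


# --- export -----------------------------------------------------------------

def _g(x: Optional[float]) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return NOT_ESTIMABLE_SENTINEL
    return format(x, ".6g")


def _estimate_row(report: MRReport, method: str) -> list[str]:
    est = report.estimates.get(method)
    head = [report.exposure_name, report.outcome_name, report.direction, method]
    if est is None:
        return head + [NOT_ESTIMABLE_SENTINEL] * 5
    return head + [str(est.nsnp), _g(est.or_), _g(est.ci_low), _g(est.ci_high), _g(est.pval)]


def export_reports(reports: list[MRReport], outdir: str | Path, cfg: RunConfig) -> None:
    """Write estimate, sensitivity, audit, leave-one-out, and scatter tables
    plus a machine-readable run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    est_lines = ["exposure\toutcome\tdirection\tmethod\tnsnp\tOR\tlower\tupper\tpval"]
    for rep in reports:
        for method in ("IVW", "MR-Egger", "WME"):
            est_lines.append("\t".join(_estimate_row(rep, method)))
    (outdir / "estimates.tsv").write_text("\n".join(est_lines) + "\n")

    sens_lines = [
        "exposure\toutcome\tdirection\tQ_IVW\tP_Q_IVW\tQ_Egger\tP_Q_Egger\tintercept\tP_intercept"
    ]
    for rep in reports:
        qi = rep.heterogeneity.get("IVW")
        qe = rep.heterogeneity.get("MR-Egger")
        pl = rep.pleiotropy
        sens_lines.append(
            "\t".join(
                [
                    rep.exposure_name, rep.outcome_name, rep.direction,
                    _g(qi.q) if qi else NOT_ESTIMABLE_SENTINEL,
                    _g(qi.pval) if qi else NOT_ESTIMABLE_SENTINEL,
                    _g(qe.q) if qe else NOT_ESTIMABLE_SENTINEL,
                    _g(qe.pval) if qe else NOT_ESTIMABLE_SENTINEL,
                    _g(pl.intercept) if pl else NOT_ESTIMABLE_SENTINEL,
                    _g(pl.pval) if pl else NOT_ESTIMABLE_SENTINEL,
                ]
            )
        )
    (outdir / "sensitivity.tsv").write_text("\n".join(sens_lines) + "\n")

    loo_lines = ["exposure\toutcome\tdirection\tdropped_snp\ttheta\tse\tOR\tlower\tupper\tpval"]
    for rep in reports:
        if rep.loo is None:
            continue
        full = rep.loo.full
        loo_lines.append(
            "\t".join(
                [rep.exposure_name, rep.outcome_name, rep.direction, "ALL",
                 _g(full.theta), _g(full.se), _g(full.or_), _g(full.ci_low),
                 _g(full.ci_high), _g(full.pval)]
            )
        )
        for snp_id, est in rep.loo.estimates.items():
            loo_lines.append(
                "\t".join(
                    [rep.exposure_name, rep.outcome_name, rep.direction, snp_id,
                     _g(est.theta), _g(est.se), _g(est.or_), _g(est.ci_low),
                     _g(est.ci_high), _g(est.pval)]
                )
            )
    (outdir / "leave_one_out.tsv").write_text("\n".join(loo_lines) + "\n")

    for rep in reports:
        write_harmonization_audit(rep.harmonized, outdir / f"audit_{rep.pair_label}.tsv")
        scatter = ["snp_id\tbeta_exp\tse_exp\tbeta_out\tse_out"]
        for h in surviving(rep.harmonized):
            scatter.append(
                f"{h.snp_id}\t{_g(h.beta_exp)}\t{_g(h.se_exp)}\t{_g(h.beta_out)}\t{_g(h.se_out)}"
            )
        (outdir / f"scatter_{rep.pair_label}.tsv").write_text("\n".join(scatter) + "\n")

    presso_lines = [
        "exposure\toutcome\tdirection\tglobal_rss\tglobal_pval\toutliers\tdistortion_pval\tcorrected_OR"
    ]
    for rep in reports:
        pr = rep.presso
        if pr is None:
            presso_lines.append(
                "\t".join([rep.exposure_name, rep.outcome_name, rep.direction]
                          + [NOT_ESTIMABLE_SENTINEL] * 5)
            )
            continue
        presso_lines.append(
            "\t".join(
                [
                    rep.exposure_name, rep.outcome_name, rep.direction,
                    _g(pr.global_rss), _g(pr.global_pval),
                    ",".join(sorted(pr.outliers)) if pr.outliers else "none",
                    _g(pr.distortion_pval) if pr.distortion_pval is not None
                    else NOT_ESTIMABLE_SENTINEL,
                    _g(pr.corrected.or_) if pr.corrected is not None
                    else NOT_ESTIMABLE_SENTINEL,
                ]
            )
        )
    (outdir / "presso.tsv").write_text("\n".join(presso_lines) + "\n")

    manifest = {
        "tsmr_version": __version__,
        "seed": cfg.seed,
        "config": cfg.raw,
        "pairs": [rep.pair_label for rep in reports],
        "significant": [
            [rep.exposure_name, rep.outcome_name]
            for rep in reports
            if rep.significant and rep.direction == "forward"
        ],
        "errors": {rep.pair_label: rep.error for rep in reports if rep.error},
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
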