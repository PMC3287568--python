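"""End-to-end orchestration: CFR -> FFS -> model selection -> survival.

A :class:`PipelineConfig` (TOML on disk) fully determines a run: input
paths, the recurrence cutoff, the CFR cutoffs, the FFS run count and
retention grid, the model families and latent-variable range, the
cross-validation scheme, and one master seed from which every stage seed
is derived.  ``run_pipeline`` executes the stages in order and writes a
run directory of text artifacts (retained feature lists, the model grid,
out-of-fold predictions, Kaplan-Meier tables, and a JSON summary stamped
with the config hash), so a rerun with the same config and seed is
byte-identical apart from log timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import PlsprogError, ValidationError
from .ep import GeneSpec, ParameterSpace, ep_optimize
from .evaluation import ModelConfig, cross_validate, select_model
from .feature_reduction import cfr_filter, ffs_select
from .io_formats import (
    build_labeled_dataset, clean_expression, read_clinical, read_expression,
)
from .kernels import KernelSpec
from .survival import evaluate_prognosis_groups, format_pvalue

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CFRBlock:
    p_cutoff: float = 0.05
    cv_cutoff: float = 0.632
    direction: str = "above"


@dataclass(frozen=True)
class FFSBlock:
    runs: int = 1000
    p_grid: tuple[int, ...] = tuple(range(50, 551, 50))
    split_fraction: float = 2 / 3
    settings: tuple[int, ...] = (20, 30, 150)


@dataclass(frozen=True)
class ModelBlock:
    families: tuple[str, ...] = ("lpls", "kpls")
    kernel_family: str = "polynomial"
    kernel_degree: int = 1
    kernel_sigma: float = 1.0
    M_min: int = 1
    M_max: int = 5


@dataclass(frozen=True)
class CVBlock:
    k: int = 5
    scheme: str = "kfold"
    mode: str = "paper"  # "paper": selection before CV; "nested": in-fold


@dataclass(frozen=True)
class EPBlock:
    enabled: bool = False
    pop_size: int = 20
    generations: int = 50
    q: int = 10


@dataclass(frozen=True)
class PipelineConfig:
    expression_path: str = ""
    clinical_path: str = ""
    output_dir: str = "plsprog_run"
    cutoff_months: float = 36.0
    use_covariates: bool = False
    plot: bool = False
    seed: int = 0
    cfr: CFRBlock = field(default_factory=CFRBlock)
    ffs: FFSBlock = field(default_factory=FFSBlock)
    model: ModelBlock = field(default_factory=ModelBlock)
    cv: CVBlock = field(default_factory=CVBlock)
    ep: EPBlock = field(default_factory=EPBlock)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ValidationError(f"cannot serialize config value {v!r}")


def config_to_toml(config: PipelineConfig) -> str:
    """Serialize a config to TOML; inverse of :func:`config_from_toml`."""
    top, sections = [], []
    for name, value in asdict(config).items():
        if isinstance(value, dict):
            lines = [f"[{name}]"]
            lines += [f"{k} = {_toml_value(v)}" for k, v in value.items()]
            sections.append("\n".join(lines))
        else:
            top.append(f"{name} = {_toml_value(value)}")
    return "\n".join(top) + "\n\n" + "\n\n".join(sections) + "\n"


_BLOCKS = {"cfr": CFRBlock, "ffs": FFSBlock, "model": ModelBlock,
           "cv": CVBlock, "ep": EPBlock}


def config_from_dict(data: dict) -> PipelineConfig:
    kwargs = {}
    for key, value in data.items():
        if key in _BLOCKS:
            value = {k: tuple(v) if isinstance(v, list) else v
                     for k, v in value.items()}
            kwargs[key] = _BLOCKS[key](**value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def config_from_toml(path) -> PipelineConfig:
    with open(path, "rb") as fh:
        return config_from_dict(tomllib.load(fh))


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config_to_toml(config).encode()).hexdigest()[:16]


def _model_families(config: PipelineConfig) -> list[ModelConfig]:
    kernel = KernelSpec(
        family=config.model.kernel_family,
        degree=config.model.kernel_degree,
        sigma=config.model.kernel_sigma,
    )
    families = []
    for name in config.model.families:
        if name == "lpls":
            families.append(ModelConfig(family="lpls", M=1))
        elif name == "kpls":
            families.append(ModelConfig(family="kpls", M=1, kernel=kernel))
        else:
            raise ValidationError(f"unknown model family {name!r} in config")
    return families


def _stage_seeds(master: int, n: int = 6) -> list[int]:
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


@dataclass
class PipelineResult:
    """Key numbers and artifact locations from one pipeline run."""

    output_dir: Path
    n_samples_labeled: int
    n_features_initial: int
    n_features_cfr: int
    n_features_ffs: int | None
    best_family: str
    best_M: int
    best_p: int | None
    validation_auc: float
    logrank_chi2: float
    logrank_p: float
    cox_hr: float
    cox_ci95: tuple[float, float]
    summary: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order; see the module docstring."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("plsprog")
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, out)
    except PlsprogError:
        logger.exception("pipeline aborted")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline(config: PipelineConfig, out: Path) -> PipelineResult:
    chash = config_hash(config)
    seeds = _stage_seeds(config.seed)
    logger.info("pipeline start: config %s seed %d", chash, config.seed)
    (out / "config.toml").write_text(config_to_toml(config))

    # --- stage: load and clean -------------------------------------------
    xm = clean_expression(read_expression(config.expression_path))
    clinical = read_clinical(config.clinical_path)
    dataset = build_labeled_dataset(
        xm, clinical, config.cutoff_months, use_covariates=config.use_covariates
    )
    n_pos = int(np.sum(dataset.y == 1))
    logger.info(
        "labeled dataset: %d samples (%d high risk) x %d features at "
        "cutoff %.0f months",
        dataset.X.n_samples, n_pos, dataset.X.n_features, config.cutoff_months,
    )
    labels_df = dataset.X.to_frame().index.to_frame(name="sample_id")
    labels_df["label"] = dataset.y.astype(int)
    labels_df.to_csv(out / "labels.tsv", sep="\t", index=False)

    # --- stage: coarse feature reduction ---------------------------------
    cfr_ids = cfr_filter(
        dataset.X, dataset.y,
        p_cutoff=config.cfr.p_cutoff, cv_cutoff=config.cfr.cv_cutoff,
        direction=config.cfr.direction,
    )
    if len(cfr_ids) < 2:
        raise ValidationError(
            f"CFR retained only {len(cfr_ids)} features; relax the cutoffs"
        )
    logger.info("CFR: %d -> %d features", dataset.X.n_features, len(cfr_ids))
    (out / "cfr_features.txt").write_text("\n".join(cfr_ids) + "\n")
    X_cfr = dataset.X.subset_features(cfr_ids)

    # --- stage: FFS + model selection ------------------------------------
    p_grid = [p for p in config.ffs.p_grid if p <= len(cfr_ids)]
    if not p_grid:
        logger.info("no retention size <= %d; using the CFR set directly",
                    len(cfr_ids))
        p_grid = None
    report = select_model(
        X_cfr, dataset.y,
        families=_model_families(config),
        M_range=range(config.model.M_min, config.model.M_max + 1),
        p_grid=p_grid,
        ffs_runs=config.ffs.runs,
        ffs_split=config.ffs.split_fraction,
        ffs_settings=config.ffs.settings,
        k=config.cv.k, scheme=config.cv.scheme, seed=seeds[0],
    )
    report.grid.to_csv(out / "model_selection.tsv", sep="\t", index=False)
    if report.ffs_scores is not None:
        report.ffs_scores.to_csv(out / "ffs_scores.tsv", sep="\t", index=False)
    ffs_ids = report.best_features
    (out / "ffs_features.txt").write_text("\n".join(ffs_ids) + "\n")
    logger.info(
        "model selection: %s with M=%d on %s features (AUC %.3f)",
        report.best_config.label, report.best_config.M,
        "all CFR" if report.best_p is None else f"p={report.best_p}",
        report.best_auc,
    )

    # --- stage: optional EP kernel search --------------------------------
    ep_summary = None
    if config.ep.enabled:
        ep_summary = _run_ep_stage(config, out, X_cfr, dataset.y, ffs_ids,
                                   report, seeds[2])

    # --- stage: final cross-validated predictions ------------------------
    X_final = X_cfr.subset_features(ffs_ids)
    selector = None
    X_for_cv = X_final
    if config.cv.mode == "nested":
        X_for_cv = dataset.X  # selection happens inside each fold
        selector = _nested_selector(config, report.best_p, seeds[3],
                                    list(dataset.X.feature_ids))
    cv = cross_validate(
        X_for_cv, dataset.y, report.best_config,
        k=config.cv.k, scheme=config.cv.scheme, seed=seeds[1],
        selector=selector,
    )
    pred = dataset.X.to_frame().index.to_frame(name="sample_id")
    pred["oof_score"] = cv.oof_scores
    pred["predicted_group"] = np.where(cv.oof_scores > 0, "high", "low")
    pred["label"] = dataset.y.astype(int)
    pred.to_csv(out / "predictions.tsv", sep="\t", index=False)

    # --- stage: survival evaluation of predicted groups ------------------
    clin = clinical.indexed().loc[dataset.X.sample_ids]
    evaluation = evaluate_prognosis_groups(
        clin["time_months"].to_numpy(), clin["event"].to_numpy(),
        cv.oof_scores,
    )
    evaluation.curve_high.to_frame().to_csv(out / "km_high.tsv", sep="\t", index=False)
    evaluation.curve_low.to_frame().to_csv(out / "km_low.tsv", sep="\t", index=False)
    if config.plot:
        _plot_km(evaluation, out / "km.png", config.cutoff_months)
    logger.info(
        "survival: log-rank chi2 %.2f (p %s), hazard ratio %.3f (%.3f-%.3f)",
        evaluation.logrank_chi2, evaluation.logrank_p_text,
        evaluation.cox.hr, *evaluation.cox.ci95,
    )

    summary = {
        "package_version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "cutoff_months": config.cutoff_months,
        "n_samples_labeled": dataset.X.n_samples,
        "n_high_risk": n_pos,
        "n_features_initial": dataset.X.n_features,
        "n_features_cfr": len(cfr_ids),
        "n_features_ffs": None if report.best_p is None else len(ffs_ids),
        "best_family": report.best_config.label,
        "best_M": report.best_config.M,
        "best_p": report.best_p,
        "selection_auc": report.best_auc,
        "validation_auc": cv.mean_auc,
        "fold_aucs": cv.fold_aucs,
        "logrank_chi2": evaluation.logrank_chi2,
        "logrank_p": evaluation.logrank_p,
        "logrank_p_text": evaluation.logrank_p_text,
        "cox_hr": evaluation.cox.hr,
        "cox_log_hr": evaluation.cox.log_hr,
        "cox_ci95": list(evaluation.cox.ci95),
        "ep": ep_summary,
    }
    (out / "run.json").write_text(json.dumps(summary, indent=2) + "\n")
    logger.info("pipeline done: validation AUC %.3f", cv.mean_auc)
    return PipelineResult(
        output_dir=out,
        n_samples_labeled=dataset.X.n_samples,
        n_features_initial=dataset.X.n_features,
        n_features_cfr=len(cfr_ids),
        n_features_ffs=summary["n_features_ffs"],
        best_family=report.best_config.label,
        best_M=report.best_config.M,
        best_p=report.best_p,
        validation_auc=cv.mean_auc,
        logrank_chi2=evaluation.logrank_chi2,
        logrank_p=evaluation.logrank_p,
        cox_hr=evaluation.cox.hr,
        cox_ci95=evaluation.cox.ci95,
        summary=summary,
    )


def _nested_selector(config: PipelineConfig, p: int | None, seed: int,
                     feature_ids: list[str]):
    """CFR + FFS re-run inside each training fold (selection-bias control)."""
    id_pos = {f: j for j, f in enumerate(feature_ids)}

    def selector(X_train, y_train):
        ids = cfr_filter(
            X_train, y_train,
            p_cutoff=config.cfr.p_cutoff, cv_cutoff=config.cfr.cv_cutoff,
            direction=config.cfr.direction,
        )
        cols = np.array([int(i) for i in ids])
        if p is not None and p <= len(cols):
            table = ffs_select(
                X_train[:, cols], y_train, runs=config.ffs.runs, p=p,
                split_fraction=config.ffs.split_fraction, seed=seed,
                settings=config.ffs.settings,
            )
            cols = cols[[int(i) for i in table.union]]
        return cols

    return selector


def _run_ep_stage(config, out, X_cfr, y, ffs_ids, report, seed) -> dict:
    """Evolve kernel family/parameters for K-PLS on the selected features."""
    from .evaluation import ModelConfig as MC

    X = X_cfr.subset_features(ffs_ids).values
    space = ParameterSpace(
        genes=(
            GeneSpec("log10_sigma", -2.0, 2.0),
            GeneSpec("degree", 1, 5, integer=True),
            GeneSpec("M", config.model.M_min, config.model.M_max, integer=True),
        ),
        families=("dot", "polynomial", "gaussian_rbf", "exponential_rbf"),
    )
    cv_seed = seed

    def objective(cand):
        log_sigma, degree, M = cand.gamma
        kernel = KernelSpec(family=cand.family, degree=int(degree),
                            sigma=float(10.0**log_sigma))
        cfg = MC(family="kpls", M=int(M), kernel=kernel)
        return cross_validate(X, y, cfg, k=config.cv.k, seed=cv_seed).mean_auc

    best, history = ep_optimize(
        objective, space, pop_size=config.ep.pop_size,
        generations=config.ep.generations, q=config.ep.q, seed=seed,
    )
    history.to_csv(out / "ep_history.csv", index=False)
    logger.info("EP best kernel: %s (AUC %.3f)", best.params, best.fitness)
    if best.fitness > report.best_auc:
        kernel = KernelSpec(
            family=best.params["family"], degree=best.params["degree"],
            sigma=10.0 ** best.params["log10_sigma"],
        )
        report.best_config = ModelConfig(
            family="kpls", M=best.params["M"], kernel=kernel)
        report.best_auc = best.fitness
        logger.info("EP kernel replaces grid choice")
    return {"best": best.params, "fitness": best.fitness}


def _plot_km(evaluation, path, cutoff) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve, label, color in (
        (evaluation.curve_high, "predicted high risk", "tab:red"),
        (evaluation.curve_low, "predicted low risk", "tab:blue"),
    ):
        t = np.concatenate([[0], np.repeat(curve.event_times, 2)])
        s = np.concatenate([[1, 1], np.repeat(curve.survival, 2)[:-1]])
        ax.plot(t, s, color=color, label=label)
        marks = [curve.survival_at(c) for c in curve.censor_times]
        ax.plot(curve.censor_times, marks, "+", color=color, ms=6)
    ax.set_xlabel("months")
    ax.set_ylabel("recurrence-free fraction")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(
        f"log-rank p {format_pvalue(evaluation.logrank_p)}, "
        f"HR {evaluation.cox.hr:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
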