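"""End-to-end pairwise comparison: data -> preprocessing -> five classifiers
-> interpretability -> clustering -> report.

``run_comparison`` executes one two-sample comparison on both spectral
windows and returns a :class:`ComparisonReport` holding the 5 x 2 grid of
cross-validated ROC-AUCs (with SEMs), the per-region clustering MCC and
confusion densities, permutation-importance and saliency summaries, and
run metadata. ``make_roc_table`` lays several reports out as the familiar
methods-by-case AUC table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from .cnn import CNNClassifier, vanilla_gradient_saliency
from .dataset import SpectralDataset, read_dataset, resolve_region, select_region
from .errors import InvalidConfigError
from .linear import (
    LRAClassifier,
    L2DClassifier,
    PCALogisticClassifier,
    PoolingLogisticClassifier,
    cross_validate,
    default_pooling_scheme,
    permutation_importance,
)
from .preprocess import PreprocessConfig, preprocess
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["ComparisonConfig", "ComparisonReport", "run_comparison", "make_roc_table"]

METHODS = ("LRA", "L2D", "LRP", "PCA", "CNN")


@dataclass
class ComparisonConfig:
    """One pairwise comparison.

    Exactly one of ``synthetic`` (a generator config) or ``data_path``
    (a wide delimited-text file with a label column) must be given.
    """

    synthetic: SyntheticConfig | None = None
    data_path: str | Path | None = None
    case_name: str = "first vs. second"
    regions: tuple[str, ...] = ("LW", "HW")
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    methods: tuple[str, ...] = METHODS
    folds: int = 10
    seed: int = 0
    cnn_epochs: int = 50
    cnn_early_stopping: bool = True
    n_permutations: int = 30
    run_importance: bool = True
    run_saliency: bool = True
    run_clustering: bool = True
    interp_test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.data_path is None):
            raise InvalidConfigError("give exactly one of synthetic= or data_path=")
        unknown = set(m.upper() for m in self.methods) - set(METHODS)
        if unknown:
            raise InvalidConfigError(f"unknown methods {sorted(unknown)}")


@dataclass
class ComparisonReport:
    """Everything one comparison computed."""

    case_name: str
    auc: dict  # {region: {method: {"mean":, "sem":, "folds": [...]}}}
    clustering: dict  # {region: {"mcc":, "densities": [[..]]}}
    importance: dict  # {region: {"boundaries": [...], "scores": [...]}}
    saliency: dict  # {region: {"wavenumbers": [...], "mean": [...], ...}}
    metadata: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "case_name": self.case_name,
                "auc": self.auc,
                "clustering": self.clustering,
                "importance": self.importance,
                "saliency": self.saliency,
                "metadata": self.metadata,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        lines = [f"Comparison: {self.case_name}"]
        for region, per_method in self.auc.items():
            cells = "  ".join(
                f"{m}={v['mean']:.2f}±{v['sem']:.2f}" for m, v in per_method.items()
            )
            lines.append(f"  {region}: {cells}")
        for region, c in self.clustering.items():
            lines.append(f"  clustering {region}: MCC={c['mcc']:.2f}")
        lines.append(f"  removed outliers: {self.metadata.get('removed_outlier_count')}")
        return "\n".join(lines)


def _spawn_seeds(master: int, labels: list[str]) -> dict[str, int]:
    """Fan one master seed out to named per-stage 31-bit seeds."""
    children = np.random.SeedSequence(master).spawn(len(labels))
    return {lab: int(c.generate_state(1)[0] % (2**31)) for lab, c in zip(labels, children)}


def _factory(method: str, region_name: str, cfg: ComparisonConfig, seed: int):
    method = method.upper()
    if method == "LRA":
        return lambda: LRAClassifier()
    if method == "L2D":
        return lambda: L2DClassifier(seed=seed)
    if method == "LRP":
        scheme = default_pooling_scheme(region_name)
        return lambda: PoolingLogisticClassifier(scheme)
    if method == "PCA":
        return lambda: PCALogisticClassifier()
    if method == "CNN":
        return lambda: CNNClassifier(
            epochs=cfg.cnn_epochs, seed=seed, early_stopping=cfg.cnn_early_stopping
        )
    raise InvalidConfigError(f"unknown method {method!r}")


def _interp_split(ds: SpectralDataset, test_fraction: float, seed: int):
    """Stratified train/test split used for importance and saliency."""
    rng = np.random.default_rng(seed)
    test = np.zeros(ds.n_spectra, dtype=bool)
    for lab in (0, 1):
        idx = np.flatnonzero(ds.labels == lab)
        n_test = max(1, int(round(test_fraction * idx.size)))
        test[rng.choice(idx, size=n_test, replace=False)] = True
    return ds.subset_rows(~test), ds.subset_rows(test)


def run_comparison(config: ComparisonConfig) -> ComparisonReport:
    """Execute one full pairwise comparison (see module docstring)."""
    labels = ["data"]
    for r in config.regions:
        labels += [f"cv:{r}:{m}" for m in config.methods]
        labels += [f"split:{r}", f"imp:{r}", f"clu:{r}"]
    seeds = _spawn_seeds(config.seed, labels)

    if config.synthetic is not None:
        from dataclasses import replace

        ds = generate_dataset(replace(config.synthetic, seed=seeds["data"]))
        case = config.case_name
    else:
        ds = read_dataset(config.data_path)
        case = config.case_name
    ds, prep_log = preprocess(ds, config.preprocess)

    auc: dict = {}
    clustering: dict = {}
    importance: dict = {}
    saliency: dict = {}
    for region_spec in config.regions:
        region = resolve_region(region_spec)
        rname = region.name or str(region_spec)
        sub = select_region(ds, region)
        auc[rname] = {}
        for method in config.methods:
            seed = seeds[f"cv:{rname}:{method}"]
            cv = cross_validate(_factory(method, rname, config, seed), sub, k=config.folds, seed=seed)
            auc[rname][method.upper()] = {
                "mean": cv.mean_auc,
                "sem": cv.sem,
                "folds": cv.fold_aucs.tolist(),
            }
        if config.run_importance and "LRP" in [m.upper() for m in config.methods]:
            tr, te = _interp_split(sub, config.interp_test_fraction, seeds[f"split:{rname}"])
            scheme = default_pooling_scheme(rname) if rname in ("LW", "HW") else None
            if scheme is not None:
                clf = PoolingLogisticClassifier(scheme).fit(tr)
                imp = permutation_importance(
                    clf.feature_scores,
                    clf.featurize(te),
                    te.labels,
                    n_perm=config.n_permutations,
                    seed=seeds[f"imp:{rname}"],
                )
                importance[rname] = {
                    "boundaries": list(scheme.boundaries),
                    "scores": imp.scores.tolist(),
                    "dispersions": imp.dispersions.tolist(),
                    "baseline_auc": imp.baseline_auc,
                }
        if config.run_saliency and "CNN" in [m.upper() for m in config.methods]:
            tr, te = _interp_split(sub, config.interp_test_fraction, seeds[f"split:{rname}"])
            cnn = CNNClassifier(
                epochs=config.cnn_epochs,
                seed=seeds[f"cv:{rname}:CNN"],
                early_stopping=config.cnn_early_stopping,
            ).fit(tr)
            smap = vanilla_gradient_saliency(cnn.model, te)
            saliency[rname] = {
                "wavenumbers": smap.wavenumbers.tolist(),
                "mean": smap.mean.tolist(),
                "lo95": smap.lo95.tolist(),
                "hi95": smap.hi95.tolist(),
            }
        if config.run_clustering:
            Z = _cluster.standardize_rows(sub.intensities)
            kappa = _cluster.cosine_affinity(Z)
            pred = _cluster.spectral_clustering(kappa, k=2, seed=seeds[f"clu:{rname}"])
            cm, score = _cluster.evaluate_clustering(pred, sub.labels)
            clustering[rname] = {"mcc": score, "densities": cm.densities.tolist()}

    metadata = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "stage_order": prep_log["stage_order"],
        "removed_outlier_count": len(prep_log["removed_outliers"]),
        "removed_outliers": prep_log["removed_outliers"],
        "n_spectra": ds.n_spectra,
        "folds": config.folds,
    }
    return ComparisonReport(
        case_name=case,
        auc=auc,
        clustering=clustering,
        importance=importance,
        saliency=saliency,
        metadata=metadata,
    )


def make_roc_table(reports: list[ComparisonReport]) -> pd.DataFrame:
    """Methods-by-(case, region) AUC table, rounded to 2 decimals."""
    if not reports:
        raise InvalidConfigError("need at least one report")
    rows = []
    for rep in reports:
        for region, per_method in rep.auc.items():
            row = {"case": f"{rep.case_name} {region}"}
            for method in METHODS:
                if method in per_method:
                    row[method] = round(per_method[method]["mean"], 2)
            rows.append(row)
    return pd.DataFrame(rows).set_index("case")
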