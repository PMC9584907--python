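"""Computational topology validation.

For every unordered sample pair and every gene in the pair's top-expressed
union, the cross-sample expression log-ratio of the gene (response) is
predicted from the log-ratios of the TFs (features), where a TF's
expression is replaced by a small floor in any sample whose topology lacks
the TF->gene edge.  A 10-fold cross-validated random forest measures
held-out Pearson R; the same procedure on row-wise shuffled features gives
the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .io_formats import ExpressionMatrix, ValidationError
from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass
class ValidationDesign:
    top_n: int = 500        # top expressed genes per sample
    floor: float = 1e-2     # replaces zero/absent expression
    folds: int = 10
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        if self.floor <= 0:
            raise ValidationError("floor must be positive")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")


@dataclass
class ValidationReport:
    fold_r: list[float]
    mean_r: float
    n_rows: int
    n_features: int
    shuffled: bool = False
    excluded_folds: int = 0

    def to_dict(self) -> dict:
        return {
            "fold_r": self.fold_r,
            "mean_r": self.mean_r,
            "n_rows": self.n_rows,
            "n_features": self.n_features,
            "shuffled": self.shuffled,
            "excluded_folds": self.excluded_folds,
        }


def _top_genes(tpm: pd.Series, n: int) -> set[str]:
    """Top-n genes by expression; ties break lexicographically."""
    order = sorted(tpm.index, key=lambda g: (-tpm[g], g))
    return set(order[:n])


def build_feature_matrix(networks: dict[str, RegulatoryNetwork],
                         expression: ExpressionMatrix,
                         design: ValidationDesign,
                         tf_names: list[str] | None = None
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Stacked (pair, gene) x TF feature matrix and response vector.

    Feature for TF f in row (pair (p, q), gene g):
        log2(x_p / x_q) with x = TPM of f, replaced by the floor in a
        sample whose topology lacks the edge f->g, and any zero expression
        floored before the ratio.  Response: log2 gene TPM ratio with the
        same flooring.
    """
    samples = sorted(networks)
    if len(samples) < 2:
        raise ValidationError("need >= 2 samples")
    tpm = expression.tpm
    if tf_names is None:
        tf_names = sorted({e.parent for net in networks.values()
                           for e in net.edges})
    floor = design.floor

    tops = {s: _top_genes(tpm[s], design.top_n) for s in samples}
    edge_sets = {s: networks[s].edge_set() for s in samples}

    tf_expr = {}
    for s in samples:
        vals = np.array([tpm.at[tf, s] if tf in tpm.index else 0.0
                         for tf in tf_names])
        tf_expr[s] = np.where(vals <= 0, floor, vals)

    rows = []
    responses = []
    index = []
    for i, p in enumerate(samples):
        for q in samples[i + 1:]:
            universe = sorted(tops[p] | tops[q])
            for g in universe:
                if g not in tpm.index:
                    raise ValidationError(f"gene {g} missing from expression")
                xp = tf_expr[p].copy()
                xq = tf_expr[q].copy()
                for j, tf in enumerate(tf_names):
                    if (tf, g) not in edge_sets[p]:
                        xp[j] = floor
                    if (tf, g) not in edge_sets[q]:
                        xq[j] = floor
                rows.append(np.log2(xp / xq))
                gp = tpm.at[g, p] or floor
                gq = tpm.at[g, q] or floor
                responses.append(np.log2(max(gp, floor) / max(gq, floor)))
                index.append(f"{p}|{q}|{g}")
    X = pd.DataFrame(np.array(rows), columns=tf_names,
                     index=pd.Index(index, name="pair_gene"))
    y = pd.Series(responses, index=X.index, name="log2_ratio")
    return X, y


def crossval_rf(X: pd.DataFrame, y: pd.Series,
                design: ValidationDesign) -> ValidationReport:
    """K-fold cross-validated random-forest regression; per-fold Pearson R
    on held-out rows, folds with undefined R excluded (logged)."""
    n = len(y)
    if n < design.folds:
        raise ValidationError(
            f"{n} rows < {design.folds} folds")
    kf = KFold(n_splits=design.folds, shuffle=True, random_state=design.seed)
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    fold_r: list[float] = []
    excluded = 0
    for train, test in kf.split(Xv):
        rf = RandomForestRegressor(n_estimators=design.n_trees,
                                   random_state=design.seed, n_jobs=1)
        rf.fit(Xv[train], yv[train])
        pred = rf.predict(Xv[test])
        if np.std(yv[test]) == 0 or np.std(pred) == 0:
            excluded += 1
            logger.info("fold with constant response/prediction excluded")
            continue
        fold_r.append(float(pearsonr(yv[test], pred)[0]))
    if not fold_r:
        raise ValidationError("no fold produced a defined Pearson R")
    return ValidationReport(fold_r=fold_r,
                            mean_r=float(np.mean(fold_r)),
                            n_rows=n, n_features=X.shape[1],
                            excluded_folds=excluded)


def shuffled_baseline(X: pd.DataFrame, y: pd.Series,
                      design: ValidationDesign) -> ValidationReport:
    """Independently permute feature values within each row, then run the
    identical cross-validation."""
    rng = np.random.default_rng(design.seed)
    values = X.to_numpy(dtype=float).copy()
    for i in range(values.shape[0]):
        rng.shuffle(values[i])
    Xs = pd.DataFrame(values, index=X.index, columns=X.columns)
    report = crossval_rf(Xs, y, design)
    report.shuffled = True
    return report
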