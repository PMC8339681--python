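"""Per-sample read-confidence model.

For each sample a penalized logistic regression is trained to estimate p-hat,
the probability that a spliced alignment reflects true RNA expression.
Training labels come from genomic-alignment status alone: junctional reads
*without* a contiguous alignment elsewhere are positives (y=1), those *with*
one are negatives (y=0).  That criterion is deliberately not among the
predictors, so no single predictor is privileged by construction.

The single-end design matrix holds as_norm, NH, nmm, overlap, max_overlap,
their product overlap*max_overlap, soft-clip total and 5-mer entropy; the
paired design adds the mate's copies plus the two fragment-compatibility
indicators.  Features are standardized on the training set (center/scale
frozen for scoring); the penalty is an L1 (lasso) term with strength chosen
by 10-fold cross-validated deviance under seeded fold assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from splicecall.alignment_io import (
    ReadFeatureVector,
    SplicedAlignmentRecord,
    features_for_records,
)

P_HAT_CLIP = 1e-6  # p-hat clipped to [eps, 1-eps]: log-odds must stay finite


def _predictor_names(mode: str) -> list[str]:
    base = [
        "as_norm", "nh", "nmm", "overlap", "max_overlap",
        "overlap_x_max_overlap", "softclip_s", "entropy",
    ]
    if mode == "single":
        return base
    return base + [
        "mate_as_norm", "mate_nh", "mate_nmm", "mate_overlap",
        "mate_max_overlap", "mate_overlap_x_max_overlap",
        "mate_softclip_s", "mate_entropy",
        "location_compatible", "strand_compatible",
    ]


def design_matrix(features: list[ReadFeatureVector], mode: str) -> np.ndarray:
    """Feature vectors -> design matrix with the interaction columns."""
    rows = []
    for f in features:
        row = [
            f.as_norm, f.nh, f.nmm, f.overlap, f.max_overlap,
            f.overlap * f.max_overlap, f.softclip_s, f.entropy,
        ]
        if mode == "paired":
            row += [
                f.mate_as_norm, f.mate_nh, f.mate_nmm, f.mate_overlap,
                f.mate_max_overlap, f.mate_overlap * f.mate_max_overlap,
                f.mate_softclip_s, f.mate_entropy,
                f.location_compatible, f.strand_compatible,
            ]
        rows.append(row)
    return np.asarray(rows, dtype=float)


@dataclass
class TrainingSet:
    positives: list  # (record, ReadFeatureVector), y = 1: no genomic alignment
    negatives: list  # (record, ReadFeatureVector), y = 0: genomic alignment
    cap: int
    seed: int

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.positives), len(self.negatives)


@dataclass
class FittedReadModel:
    """Coefficients and frozen standardization of one sample's model."""

    coefficients: dict  # predictor name -> value, plus "intercept"
    mode: str
    center: np.ndarray
    scale: np.ndarray
    c_selected: float  # inverse regularization strength at the CV optimum
    penalty: str
    seed: int

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        names = _predictor_names(self.mode)
        beta = np.array([self.coefficients[n] for n in names])
        Z = (X - self.center) / self.scale
        return self.coefficients["intercept"] + Z @ beta

    def predict_p_hat(self, X: np.ndarray) -> np.ndarray:
        eta = self.linear_predictor(X)
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.clip(p, P_HAT_CLIP, 1.0 - P_HAT_CLIP)

    def to_yaml(self) -> str:
        doc = {
            "mode": self.mode,
            "penalty": self.penalty,
            "c_selected": float(self.c_selected),
            "seed": int(self.seed),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "standardization": {
                "center": [float(v) for v in self.center],
                "scale": [float(v) for v in self.scale],
                "predictors": _predictor_names(self.mode),
            },
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "FittedReadModel":
        doc = yaml.safe_load(text)
        return cls(
            coefficients=doc["coefficients"],
            mode=doc["mode"],
            center=np.array(doc["standardization"]["center"]),
            scale=np.array(doc["standardization"]["scale"]),
            c_selected=doc["c_selected"],
            penalty=doc["penalty"],
            seed=doc["seed"],
        )


def build_training_set(
    records: list[SplicedAlignmentRecord],
    features: list[ReadFeatureVector],
    cap: int = 10_000,
    seed: int = 0,
) -> TrainingSet:
    """Split records into training classes by genomic-alignment status.

    A class larger than ``cap`` is reduced to a uniform random subset of
    exactly ``cap`` members drawn with the given seed.
    """
    pos = [(r, f) for r, f in zip(records, features) if not r.has_genomic_alignment]
    neg = [(r, f) for r, f in zip(records, features) if r.has_genomic_alignment]
    if not pos or not neg:
        raise ValueError(
            f"untrainable sample: {len(pos)} positive and {len(neg)} negative "
            "training reads (both classes must be non-empty)"
        )
    rng = np.random.default_rng(seed)
    if len(pos) > cap:
        idx = rng.choice(len(pos), size=cap, replace=False)
        pos = [pos[i] for i in sorted(idx)]
    if len(neg) > cap:
        idx = rng.choice(len(neg), size=cap, replace=False)
        neg = [neg[i] for i in sorted(idx)]
    return TrainingSet(positives=pos, negatives=neg, cap=cap, seed=seed)


def fit_read_model(
    training: TrainingSet,
    mode: str = "single",
    seed: int = 0,
    n_folds: int = 10,
) -> FittedReadModel:
    """Fit the L1-penalized logistic regression on the training classes."""
    feats = [f for _, f in training.positives] + [f for _, f in training.negatives]
    y = np.r_[
        np.ones(len(training.positives)), np.zeros(len(training.negatives))
    ]
    X = design_matrix(feats, mode)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    if np.all(scale == 0):
        raise ValueError("degenerate design: zero variance in every feature")
    scale = np.where(scale == 0, 1.0, scale)
    Z = (X - center) / scale

    folds = min(n_folds, int(min(y.sum(), (1 - y).sum())))
    folds = max(folds, 2)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
    clf = LogisticRegressionCV(
        Cs=np.logspace(-3, 3, 13),
        cv=cv,
        l1_ratios=(1.0,),  # pure lasso mixing
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=2000,
        random_state=seed % 2**31,
        refit=True,
        use_legacy_attributes=False,
    )
    clf.fit(Z, y)
    if not np.all(np.isfinite(clf.coef_)):
        raise RuntimeError(
            f"model fit did not converge: coefficients {clf.coef_!r}"
        )
    names = _predictor_names(mode)
    coeffs = dict(zip(names, clf.coef_[0]))
    coeffs["intercept"] = float(np.atleast_1d(clf.intercept_)[0])
    return FittedReadModel(
        coefficients=coeffs,
        mode=mode,
        center=center,
        scale=scale,
        c_selected=float(np.atleast_1d(clf.C_)[0]),
        penalty="l1 (lasso), 10-fold CV deviance",
        seed=seed,
    )


def score_reads(
    model: FittedReadModel,
    records: list[SplicedAlignmentRecord],
    features: list[ReadFeatureVector],
) -> np.ndarray:
    """p-hat for every junctional record of the sample, training reads
    included, clipped away from 0 and 1."""
    if not records:
        return np.array([])
    X = design_matrix(features, model.mode)
    return model.predict_p_hat(X)
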