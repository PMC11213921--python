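"""Temporal response motifs, motif triplets, transition maps, and
phenotype classification.

Every (cell, stimulus) time course is one observation (z-scored per row);
PCA + VRC-elbow k-means groups them into temporal response motifs, which are
re-indexed canonically by (peak sign, peak magnitude, peak latency) so that
inhibitory motifs come first and stronger/later excitation later.  Each cell
then carries an ordered motif triplet over the stimuli (Lct, Laa, LaaLct);
per-animal motif-transition matrices between stimulus pairs feed a
leave-one-out diagonal-covariance linear discriminant classifier of the
social phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .responses import _project_pca, choose_k_elbow, vrc_curve

__all__ = [
    "ProfileMatrix",
    "MotifSet",
    "TransitionMap",
    "build_profile_matrix",
    "cluster_motifs",
    "motif_triplets",
    "transition_probabilities",
    "classify_phenotype_loo",
    "DEFAULT_STIMULI",
    "DEFAULT_PAIRS",
]

log = logging.getLogger(__name__)

DEFAULT_STIMULI = ("Lct", "Laa", "LaaLct")
DEFAULT_PAIRS = (("Lct", "Laa"), ("Lct", "LaaLct"), ("Laa", "LaaLct"))


@dataclass
class ProfileMatrix:
    """(unit, stimulus) observations x frames, z-scored per row."""

    values: np.ndarray                  # (n_rows, n_frames)
    unit: np.ndarray                    # unit id per row
    stimulus: np.ndarray                # stimulus label per row
    animal: np.ndarray                  # animal id per row
    phenotype: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        for arr in ("unit", "stimulus", "animal"):
            setattr(self, arr, np.asarray(getattr(self, arr)))


def build_profile_matrix(traces: np.ndarray, unit, stimulus, animal,
                         phenotype=None) -> ProfileMatrix:
    """Assemble and z-score (mean 0, s.d. 1 per row) a profile matrix.

    Rows with zero variance are mapped to zeros."""
    traces = np.asarray(traces, dtype=float)
    mu = traces.mean(axis=1, keepdims=True)
    sd = traces.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return ProfileMatrix((traces - mu) / sd, unit, stimulus, animal, phenotype)


@dataclass
class MotifSet:
    templates: np.ndarray               # (k, n_frames) mean z-profile per motif
    assignment: np.ndarray              # motif id (1-based) per row
    profiles: ProfileMatrix
    order_key: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.templates.shape[0]


def _canonical_order(templates: np.ndarray) -> np.ndarray:
    """Sort motif templates by (peak sign, peak magnitude, peak latency).

    Negative-peaked (inhibitory) motifs come first, then excitatory ones by
    increasing extremum magnitude; peak latency breaks magnitude ties.
    Returns the template indices in canonical order."""
    keys = []
    for i, tpl in enumerate(templates):
        ext = tpl[np.abs(tpl).argmax()]
        sign = -1.0 if ext < 0 else 1.0
        keys.append((sign, abs(ext), int(np.abs(tpl).argmax()), i))
    return np.array([k[-1] for k in sorted(keys)])


def cluster_motifs(profiles: ProfileMatrix, k_range=range(2, 21),
                   n_replicates: int = 50, seed: int = 0,
                   variance_retained: float = 0.99) -> MotifSet:
    """PCA + VRC-elbow k-means over z-scored time courses.

    Motif ids are 1-based and canonically re-indexed; the mean z-profile per
    motif is the motif template."""
    if profiles.values.shape[1] < 3:
        raise ValueError("profiles must span at least 3 frames")
    if profiles.values.shape[0] < 2:
        raise ValueError("need at least 2 profile rows")
    X = _project_pca(profiles.values, variance_retained)
    curve, labels_by_k = vrc_curve(X, k_range, n_replicates, seed)
    if curve.k_values.size == 0:
        raise ValueError("too few rows for the requested k range")
    if curve.degenerate and not np.isfinite(curve.vrc_values).any():
        k = int(curve.k_values[0])
        log.warning("degenerate profile set (SSW=0); k forced to minimum")
    else:
        k = choose_k_elbow(curve)
    curve.chosen_k = k
    raw_labels = labels_by_k[k]
    templates = np.array([profiles.values[raw_labels == c].mean(axis=0)
                          for c in range(k)])
    order = _canonical_order(templates)
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    assignment = rank[raw_labels] + 1
    return MotifSet(templates[order], assignment, profiles, order_key=list(order))


def motif_triplets(mset: MotifSet, stimuli=DEFAULT_STIMULI) -> pd.DataFrame:
    """Per-unit ordered motif triplet [m_Lct | m_Laa | m_LaaLct].

    Units missing any stimulus row are excluded (logged).  Returns a
    DataFrame indexed by unit with one column per stimulus plus animal /
    phenotype bookkeeping."""
    prof = mset.profiles
    rows = {}
    for unit in pd.unique(prof.unit):
        sel = prof.unit == unit
        stims = prof.stimulus[sel]
        if set(stimuli) - set(stims.tolist()):
            log.info("unit %r missing a stimulus row; excluded", unit)
            continue
        rec = {}
        for s in stimuli:
            idx = np.nonzero(sel & (prof.stimulus == s))[0][0]
            rec[s] = int(mset.assignment[idx])
        rec["animal"] = prof.animal[sel][0]
        if prof.phenotype is not None:
            rec["phenotype"] = prof.phenotype[sel][0]
        rows[unit] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class TransitionMap:
    """Per-animal motif-transition matrices between ordered stimulus pairs."""

    animal: str
    phenotype: str | None
    matrices: dict                      # (stim_from, stim_to) -> (k, k)
    k: int

    def features(self, pairs=DEFAULT_PAIRS) -> np.ndarray:
        return np.concatenate([self.matrices[p].ravel() for p in pairs])


def transition_probabilities(triplets: pd.DataFrame, k: int,
                             stimulus_pairs=DEFAULT_PAIRS) -> list[TransitionMap]:
    """Joint motif-transition proportions per animal.

    For each ordered stimulus pair, entry (i, j) of the k x k matrix is the
    fraction of the animal's units assigned motif i for the first stimulus
    and motif j for the second; entries sum to 1."""
    out = []
    for animal, sub in triplets.groupby("animal", sort=True):
        mats = {}
        for s_from, s_to in stimulus_pairs:
            M = np.zeros((k, k))
            for i, j in zip(sub[s_from], sub[s_to]):
                M[i - 1, j - 1] += 1
            mats[(s_from, s_to)] = M / max(len(sub), 1)
        phen = sub["phenotype"].iloc[0] if "phenotype" in sub else None
        out.append(TransitionMap(str(animal), phen, mats, k))
    return out


def _diag_lda_fit(X: np.ndarray, y: np.ndarray):
    """Gaussian discriminant with a pooled diagonal covariance and uniform
    class priors (the prior reweighting compensates unequal group sizes)."""
    classes = np.unique(y)
    means = np.array([X[y == c].mean(axis=0) for c in classes])
    resid = np.concatenate([X[y == c] - means[i] for i, c in enumerate(classes)])
    var = resid.var(axis=0, ddof=len(classes))
    var[var <= 0] = np.finfo(float).eps
    return classes, means, var


def _diag_lda_scores(x: np.ndarray, means: np.ndarray, var: np.ndarray):
    return -0.5 * (((x - means) ** 2) / var).sum(axis=1)


def classify_phenotype_loo(tmaps: list[TransitionMap],
                           variance_retained: float = 0.83,
                           pairs=DEFAULT_PAIRS):
    """Leave-one-animal-out phenotype classification from transition maps.

    Features are the flattened transition matrices.  In each fold PCA is fit
    on the training animals only (keeping >= ``variance_retained`` cumulative
    variance) and a linear discriminant with pooled diagonal covariance and
    uniform class priors predicts the held-out animal.  A tie in the
    discriminant scores predicts the globally rarer class.  Returns
    ``(predictions, confusion, accuracy)``.
    """
    X = np.array([t.features(pairs) for t in tmaps])
    y = np.array([t.phenotype for t in tmaps])
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need at least 2 animals per phenotype")
    rarer = classes[counts.argmin()]

    preds = []
    for i in range(len(tmaps)):
        train = np.ones(len(tmaps), dtype=bool)
        train[i] = False
        y_tr = y[train]
        if np.unique(y_tr).size < 2:
            raise ValueError("single-class training fold")
        from sklearn.decomposition import PCA

        pca = PCA(n_components=min(train.sum() - 1, X.shape[1]),
                  svd_solver="full")
        Z_tr = pca.fit_transform(X[train])
        cum = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, variance_retained - 1e-12) + 1)
        keep = min(keep, Z_tr.shape[1])
        Z_tr = Z_tr[:, :keep]
        z = pca.transform(X[i:i + 1])[:, :keep][0]
        cls, means, var = _diag_lda_fit(Z_tr, y_tr)
        scores = _diag_lda_scores(z, means, var)
        if np.isclose(scores.max(), scores.min()):
            preds.append(rarer)
        else:
            preds.append(cls[scores.argmax()])
    preds = np.array(preds)
    confusion = pd.crosstab(pd.Series(y, name="true"),
                            pd.Series(preds, name="predicted"),
                            dropna=False).reindex(index=classes, columns=classes,
                                                  fill_value=0)
    accuracy = float((preds == y).mean())
    return preds, confusion, accuracy
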