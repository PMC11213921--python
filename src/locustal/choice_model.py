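"""Bayesian patch-choice model for multi-cue foraging decisions.

A locust choosing among four patches integrates four information classes
(socio-visual, food-visual, socio-olfactory, food-olfactory).  Each class i
carries a reliability parameter C_i > 0; a patch x advertises class i when the
availability entry w is 1.  The probability that patch x is "good" given class
i is

    P(x good | C_i) = 1 / (1 + C_i^(-w)),

which is 1/2 whenever the cue is absent (w = 0) or uninformative (C_i = 1).
Per-patch choice probabilities multiply the four class terms and normalize
across patches.  Fitting recovers log10(C_i) in [-1, 1] from observed
quarter-occupancy fractions; log10(C_i) is reported as the information
reliability score (positive = attraction, negative = aversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "INFO_CLASSES",
    "PATCHES",
    "CueModel",
    "ReliabilityEstimate",
    "default_availability",
    "patch_probabilities",
    "reliability_score",
    "fit_reliability",
]

INFO_CLASSES = ("socio-visual", "food-visual", "socio-olfactory", "food-olfactory")
PATCHES = ("Lvs", "Lct", "LvsLct", "Ctr")


def default_availability() -> dict[str, np.ndarray]:
    """Availability matrices W (patches x classes) for the three standard
    sensory conditions of the four-patch assay.

    Patch rows follow PATCHES (leaves, locusts, leaves+locusts, control);
    class columns follow INFO_CLASSES.  Occluding a modality zeroes the
    corresponding columns.
    """
    full = np.array(
        [
            #  s-vis f-vis s-olf f-olf
            [0, 1, 0, 1],   # Lvs
            [1, 0, 1, 0],   # Lct
            [1, 1, 1, 1],   # LvsLct
            [0, 0, 0, 0],   # Ctr
        ],
        dtype=float,
    )
    no_vis = full.copy()
    no_vis[:, [0, 1]] = 0
    no_olf = full.copy()
    no_olf[:, [2, 3]] = 0
    return {"Vis+Olf+": full, "Vis-Olf+": no_vis, "Vis+Olf-": no_olf}


@dataclass(frozen=True)
class CueModel:
    """Reliabilities C (4,) plus one availability matrix per condition."""

    C: np.ndarray
    W: dict[str, np.ndarray] = field(default_factory=default_availability)

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "C", C)
        if C.shape != (4,):
            raise ValueError("C must have four entries, one per information class")
        if np.any(C <= 0):
            raise ValueError("reliabilities C must be positive")
        for name, w in self.W.items():
            w = np.asarray(w, dtype=float)
            if not np.all(np.isin(w, (0.0, 1.0))):
                raise ValueError(f"W[{name!r}] must be binary")


@dataclass(frozen=True)
class ReliabilityEstimate:
    C_hat: np.ndarray
    score: np.ndarray          # log10(C_hat), per class
    ci95: np.ndarray           # (4, 2) percentile interval over repetitions
    n_repeats: int
    objective_value: float
    ci_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "classes": list(INFO_CLASSES),
            "score": self.score.tolist(),
            "ci95": self.ci95.tolist(),
            "n_repeats": self.n_repeats,
            "objective_value": self.objective_value,
        }


def patch_probabilities(model: CueModel, condition: str | np.ndarray) -> np.ndarray:
    """Per-patch choice probabilities under one sensory condition.

    ``condition`` is either a key into the model's W dict or an explicit
    (n_patches, 4) binary availability matrix.  Output sums to 1.
    """
    W = model.W[condition] if isinstance(condition, str) else np.asarray(condition, float)
    C = model.C
    # P(x good | C_i) = 1 / (1 + C_i^-w); w=0 gives 1/2 regardless of C
    good = 1.0 / (1.0 + C[np.newaxis, :] ** (-W))
    unnorm = good.prod(axis=1)
    return unnorm / unnorm.sum()


def reliability_score(C) -> np.ndarray:
    """Information reliability score log10(C), elementwise."""
    C = np.asarray(C, dtype=float)
    if np.any(C <= 0):
        raise ValueError("C must be positive")
    return np.log10(C)


def _sse(log_c: np.ndarray, targets: dict[str, np.ndarray], W_set) -> float:
    model = CueModel(10.0 ** log_c, W_set)
    err = 0.0
    for cond, occ in targets.items():
        err += float(np.sum((patch_probabilities(model, cond) - occ) ** 2))
    return err


def _fit_once(targets, W_set, rng, n_starts: int = 8) -> tuple[np.ndarray, float]:
    bounds = [(-1.0, 1.0)] * 4
    best_x, best_f = None, np.inf
    starts = rng.uniform(-1.0, 1.0, size=(n_starts, 4))
    starts[0] = 0.0  # always include the uninformative model
    for x0 in starts:
        res = minimize(_sse, x0, args=(targets, W_set), method="L-BFGS-B", bounds=bounds)
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    return best_x, best_f


def fit_reliability(
    occupancy: dict[str, np.ndarray],
    W_set: dict[str, np.ndarray] | None = None,
    n_repeats: int = 5000,
    seed: int = 0,
    n_starts: int = 8,
) -> ReliabilityEstimate:
    """Fit shared reliabilities C to per-animal quarter occupancies.

    Parameters
    ----------
    occupancy
        Mapping condition -> array (n_animals, 4) of quarter-occupancy
        fractions in canonical patch order; each row sums to 1.
    W_set
        Availability matrices per condition; defaults to the standard assay.
    n_repeats
        Number of fit repetitions.  Each repetition resamples animals with
        replacement and re-seeds the multistart optimizer; the reported score
        is the repetition mean with a 2.5/97.5 percentile interval.

    The squared-error objective compares model choice probabilities with the
    mean observed occupancy, jointly over conditions with a shared C, and the
    search runs on log10(C) in the box [-1, 1]^4.
    """
    if W_set is None:
        W_set = default_availability()
    occ = {}
    for cond, rows in occupancy.items():
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if np.any(~np.isfinite(rows)):
            raise ValueError(f"occupancy for {cond!r} contains NaN/inf")
        if cond not in W_set:
            raise ValueError(f"no availability matrix for condition {cond!r}")
        occ[cond] = rows
    if not occ:
        raise ValueError("no occupancy data")
    n_animals = min(rows.shape[0] for rows in occ.values())
    ci_defined = n_animals >= 2

    rng = np.random.default_rng(seed)
    targets0 = {c: rows.mean(axis=0) for c, rows in occ.items()}
    x_point, f_point = _fit_once(targets0, W_set, rng, n_starts)

    fits = np.empty((n_repeats, 4))
    for r in range(n_repeats):
        if ci_defined:
            targets = {}
            for cond, rows in occ.items():
                idx = rng.integers(0, rows.shape[0], size=rows.shape[0])
                targets[cond] = rows[idx].mean(axis=0)
        else:
            targets = targets0
        x, _ = _fit_once(targets, W_set, rng, n_starts)
        fits[r] = x

    score = fits.mean(axis=0)
    ci = np.column_stack([
        np.percentile(fits, 2.5, axis=0, method="lower"),
        np.percentile(fits, 97.5, axis=0, method="higher"),
    ])
    return ReliabilityEstimate(
        C_hat=10.0 ** score,
        score=score,
        ci95=ci,
        n_repeats=n_repeats,
        objective_value=f_point,
        ci_defined=ci_defined,
    )
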