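"""Case-control k-fold cross-validation with rank-binned Spearman statistic.

Each replicate randomly assigns 80% of strata (kept intact) to training,
refits the model, and scores every row of each validation stratum. Within
a stratum the rows are ranked ascending by predicted score (rank S =
highest; ties broken uniformly at random), and the rank of the used row is
recorded. Ranks are tallied into S bins, and the replicate's statistic is
the Spearman correlation r_s between bin index (1..S) and bin frequency.
A predictive model loads used rows into high ranks, pushing r_s toward 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .clogit import ClogitData, fit_clogit
from .design import StrataSet
from .exceptions import ConfigurationError
from .model_selection import ModelSpec

logger = logging.getLogger(__name__)


def spearman_rank_bins(freq) -> float:
    """Spearman correlation between bin index 1..S and bin frequencies.

    Average ranks are used for ties. A constant frequency vector carries
    no ordering information and returns 0 by convention.
    """
    freq = np.asarray(freq, dtype=float)
    if np.all(freq == freq[0]):
        return 0.0
    rho = spearmanr(np.arange(1, len(freq) + 1), freq).statistic
    return float(rho)


@dataclass
class CVResult:
    """Replicated cross-validation statistics."""

    rs: np.ndarray
    reps: int
    n_skipped: int
    seed: int | None

    @property
    def mean(self) -> float:
        return float(np.mean(self.rs))

    @property
    def min(self) -> float:
        return float(np.min(self.rs))

    @property
    def max(self) -> float:
        return float(np.max(self.rs))

    def to_dict(self) -> dict:
        return {
            "mean_rs": self.mean,
            "min_rs": self.min,
            "max_rs": self.max,
            "reps": self.reps,
            "n_skipped": self.n_skipped,
            "seed": self.seed,
        }


def kfold_cc(
    strata: StrataSet | ClogitData,
    model: ModelSpec | list | None = None,
    train_frac: float = 0.8,
    reps: int = 1000,
    seed: int | None = 0,
    by_cluster: bool = False,
    standardize: bool = True,
) -> CVResult:
    """Stratum-intact k-fold cross-validation.

    All strata must share one size S (= 1 used + M available). Splits are
    by strata (``by_cluster=True`` instead holds out whole individuals).
    Training refits use the full-data estimate as a warm start and the
    point estimate only. Non-convergent training fits skip the replicate
    with a logged warning.
    """
    if isinstance(strata, StrataSet):
        data = ClogitData.from_strata(strata, terms=_terms_of(model, strata),
                                      standardize=standardize)
    else:
        data = strata
    sizes = np.diff(data.starts)
    if len(np.unique(sizes)) != 1:
        raise ConfigurationError("cross-validation requires equal-size strata")
    S = int(sizes[0])
    n = data.n_strata
    n_train = int(np.ceil(train_frac * n))
    if n_train >= n:
        raise ConfigurationError("validation fold would be empty")

    rng = np.random.default_rng(seed)
    full_fit = fit_clogit(data)
    beta0 = full_fit.beta

    # used rows sit first in each stratum (ClogitData layout)
    eta_full_shape = (n, S)
    rs_values = []
    skipped = 0
    for _ in range(reps):
        if by_cluster:
            clusters = np.unique(data.cluster_of_stratum)
            rng.shuffle(clusters)
            n_ctrain = int(np.ceil(train_frac * len(clusters)))
            train_c = set(clusters[:n_ctrain])
            train_mask = np.isin(data.cluster_of_stratum, list(train_c))
            train_idx = np.flatnonzero(train_mask)
            val_idx = np.flatnonzero(~train_mask)
            if len(val_idx) == 0 or len(train_idx) == 0:
                raise ConfigurationError("cluster split produced an empty fold")
        else:
            perm = rng.permutation(n)
            train_idx, val_idx = perm[:n_train], perm[n_train:]
        try:
            fit = fit_clogit(data.subset(train_idx), init=beta0)
        except Exception as exc:  # noqa: BLE001 - any failed refit skips
            logger.warning("training fit failed (%s); replicate skipped", exc)
            skipped += 1
            continue
        if not fit.converged:
            logger.warning("training fit did not converge; replicate skipped")
            skipped += 1
            continue
        eta = (data.X @ fit.beta).reshape(eta_full_shape)[val_idx]
        # rank of the used row (column 0) with uniform random tie-breaking
        tie = rng.random(eta.shape)
        eta_u = eta[:, [0]]
        tie_u = tie[:, [0]]
        less = (eta < eta_u) | ((eta == eta_u) & (tie < tie_u))
        ranks = 1 + less.sum(axis=1)
        freq = np.bincount(ranks, minlength=S + 1)[1:]
        rs_values.append(spearman_rank_bins(freq))
    return CVResult(
        rs=np.asarray(rs_values), reps=len(rs_values), n_skipped=skipped, seed=seed
    )


def _terms_of(model, strata: StrataSet):
    if model is None:
        return None
    return model.terms if isinstance(model, ModelSpec) else list(model)
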