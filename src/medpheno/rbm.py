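"""Bernoulli restricted Boltzmann machine for medication clustering.

A binary RBM over visible units v (one per medication, per-patient receipt
indicators) and hidden units h (one per medication cluster) has energy

    E(v, h) = -a'v - c'h - v'Wh

with logistic conditionals P(h_k=1|v) = sigma(c_k + sum_i W[i,k] v_i) and
P(v_i=1|h) = sigma(a_i + sum_k W[i,k] h_k).  Training maximises the data
log-likelihood by contrastive divergence (CD-k): the intractable model
expectation in the gradient is replaced by a k-step Gibbs reconstruction
started at the data.

Medication clusters are read off the trained weights: medication i joins
hidden cluster k when clamping the one-hot visible vector e_i activates
hidden unit k above a threshold tau, i.e. sigma(W[i,k] + c_k) > tau (at
tau = 0.5 this is simply W[i,k] + c_k > 0).  A medication may join several
clusters; one that activates none falls into the residual cluster
(index n_hidden + 1), mirroring the "never activated" group.

A PCA variance profile of the same binary matrix is provided as a
dimensionality diagnostic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.decomposition import PCA

from .preprocess import BinaryMedicationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PCAProfile",
    "fit_pca",
    "RBMConfig",
    "MedicationRBM",
    "MedicationRBMResults",
    "MedicationClusterAssignment",
    "train_rbm",
    "hidden_activation",
    "assign_medication_clusters",
]


# ---------------------------------------------------------------------------
# PCA variance profiling
# ---------------------------------------------------------------------------

@dataclass
class PCAProfile:
    """Cumulative explained-variance curve with a target-variance cut."""

    n_components_grid: list[int]
    cumulative_explained_variance: list[float]
    selected_components: int
    target_variance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_components": self.n_components_grid,
                "cumulative_explained_variance": self.cumulative_explained_variance,
            }
        )


def fit_pca(matrix: BinaryMedicationMatrix, target_variance: float = 0.75) -> PCAProfile:
    """PCA variance profile of the binary matrix.

    Returns the full cumulative explained-variance curve and the smallest
    component count whose cumulative variance reaches ``target_variance``
    (default 0.75, i.e. retain ~75% of the variance).
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA requires at least 2 patients and 2 medications")
    if not 0.0 <= target_variance <= 1.0:
        raise ValueError("target_variance must lie in [0, 1]")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("matrix has zero total variance; PCA undefined")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    cum = np.minimum(cum, 1.0)
    grid = list(range(1, len(cum) + 1))
    reached = np.flatnonzero(cum >= target_variance - 1e-12)
    selected = int(grid[reached[0]]) if reached.size else int(grid[-1])
    return PCAProfile(grid, cum.tolist(), selected, target_variance)


# ---------------------------------------------------------------------------
# RBM
# ---------------------------------------------------------------------------

@dataclass
class RBMConfig:
    """CD training hyperparameters (reference-implementation defaults)."""

    learning_rate: float = 0.1
    batch_size: int = 10
    n_epochs: int = 10
    cd_steps: int = 1
    seed: int = 0


class MedicationRBM:
    """Model object: a binary RBM over a patient x medication matrix.

    Parameters
    ----------
    matrix : BinaryMedicationMatrix or array-like of {0,1}
        Training data, one row per patient.
    n_hidden : int
        Number of hidden units, i.e. non-residual medication clusters.
    """

    def __init__(self, matrix, n_hidden: int = 5):
        if isinstance(matrix, BinaryMedicationMatrix):
            self.medication_names = matrix.medication_names
            X = matrix.values.to_numpy(dtype=float)
        else:
            X = np.asarray(matrix, dtype=float)
            if X.ndim != 2:
                raise ValueError("training data must be a 2-D array")
            self.medication_names = [f"v{i}" for i in range(X.shape[1])]
        if not np.isin(X, (0.0, 1.0)).all():
            raise ValueError("RBM training data must be binary")
        if n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        self.X = X
        self.n_visible = X.shape[1]
        self.n_hidden = int(n_hidden)

    def fit(
        self,
        learning_rate: float = 0.1,
        batch_size: int = 10,
        n_epochs: int = 10,
        cd_steps: int = 1,
        seed: int = 0,
    ) -> "MedicationRBMResults":
        """Train by minibatch CD-k stochastic gradient ascent.

        Weights start from a small seeded Gaussian (sd 0.01) and hidden
        biases from zero.  Visible biases start at the data log-odds
        log(p_i/(1-p_i)) — the standard initialization for sparse binary
        data: it lets the biases model the marginals immediately, so the
        hidden units (and their biases) are left to capture co-occurrence
        rather than compensating for sparsity.  One master seed drives
        initialization, minibatch shuffling and Gibbs sampling.  The
        per-epoch mean reconstruction error is recorded as a training trace.
        """
        config = RBMConfig(learning_rate, batch_size, n_epochs, cd_steps, seed)
        if config.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")
        rng = np.random.default_rng(seed)
        # canonical (lexicographic) row order: training, and hence cluster
        # assignment, is invariant to the order patients arrive in
        X = self.X[np.lexsort(self.X.T[::-1])]
        n, nv, nh = X.shape[0], self.n_visible, self.n_hidden
        W = rng.normal(0.0, 0.01, size=(nv, nh))
        p = X.mean(axis=0).clip(1e-3, 1 - 1e-3)
        a = np.log(p / (1 - p))
        c = np.zeros(nh)
        trace: list[float] = []
        for _ in range(config.n_epochs):
            order = rng.permutation(n)
            errs = []
            for start in range(0, n, config.batch_size):
                v0 = X[order[start : start + config.batch_size]]
                dW, da, dc, err = cd_update(W, a, c, v0, config.cd_steps, rng)
                W += config.learning_rate * dW
                a += config.learning_rate * da
                c += config.learning_rate * dc
                errs.append(err)
            trace.append(float(np.mean(errs)))
        logger.info(
            "RBM trained: %d visible x %d hidden, final reconstruction error %.4f",
            nv, nh, trace[-1] if trace else float("nan"),
        )
        return MedicationRBMResults(
            W=W, visible_bias=a, hidden_bias=c,
            medication_names=list(self.medication_names),
            config=config, reconstruction_trace=trace,
        )


def cd_update(
    W: np.ndarray,
    a: np.ndarray,
    c: np.ndarray,
    v0: np.ndarray,
    cd_steps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One CD-k gradient estimate from a minibatch (ascent direction).

    Positive phase uses the exact hidden conditional at the data; the
    negative phase reconstructs v by k Gibbs half-step pairs (sample h,
    sample v) and uses the hidden conditional at the reconstruction.
    Returns (dW, da, dc, mean squared reconstruction error).
    """
    m = v0.shape[0]
    ph0 = expit(c + v0 @ W)
    h = (rng.random(ph0.shape) < ph0).astype(float)
    vk = v0
    for _ in range(cd_steps):
        pv = expit(a + h @ W.T)
        vk = (rng.random(pv.shape) < pv).astype(float)
        phk = expit(c + vk @ W)
        h = (rng.random(phk.shape) < phk).astype(float)
    dW = (v0.T @ ph0 - vk.T @ phk) / m
    da = (v0 - vk).mean(axis=0)
    dc = (ph0 - phk).mean(axis=0)
    err = float(((v0 - pv) ** 2).mean())
    return dW, da, dc, err


@dataclass
class MedicationRBMResults:
    """Fitted RBM: parameters, config and training trace.

    ``W`` is [n_visible x n_hidden]; ``visible_bias`` (a) and
    ``hidden_bias`` (c) complete the energy function.
    """

    W: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray
    medication_names: list[str]
    config: RBMConfig
    reconstruction_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.visible_bias = np.asarray(self.visible_bias, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        nv, nh = self.W.shape
        if self.visible_bias.shape != (nv,) or self.hidden_bias.shape != (nh,):
            raise ValueError("inconsistent parameter shapes")
        if not (np.isfinite(self.W).all() and np.isfinite(self.visible_bias).all()
                and np.isfinite(self.hidden_bias).all()):
            raise ValueError("non-finite RBM parameters")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def hidden_activation(self, v) -> np.ndarray:
        """P(h_k = 1 | v) for every hidden unit k."""
        v = np.asarray(v, dtype=float)
        if v.shape[-1] != self.n_visible:
            raise ValueError(
                f"visible vector has length {v.shape[-1]}, expected {self.n_visible}"
            )
        return expit(self.hidden_bias + v @ self.W)

    def visible_activation(self, h) -> np.ndarray:
        """P(v_i = 1 | h) for every visible unit i."""
        h = np.asarray(h, dtype=float)
        if h.shape[-1] != self.n_hidden:
            raise ValueError(
                f"hidden vector has length {h.shape[-1]}, expected {self.n_hidden}"
            )
        return expit(self.visible_bias + h @ self.W.T)

    def energy(self, v, h) -> float:
        """E(v, h) = -a'v - c'h - v'Wh."""
        v = np.asarray(v, dtype=float)
        h = np.asarray(h, dtype=float)
        return float(-self.visible_bias @ v - self.hidden_bias @ h - v @ self.W @ h)

    def assign_clusters(self, tau: float = 0.5) -> "MedicationClusterAssignment":
        """Threshold one-hot hidden activations into cluster memberships."""
        return assign_medication_clusters(self, tau)

    def summary(self) -> str:
        c = self.config
        lines = [
            "Medication RBM results",
            "=" * 40,
            f"visible units (medications): {self.n_visible}",
            f"hidden units (clusters):     {self.n_hidden}",
            f"training: lr={c.learning_rate} batch={c.batch_size} "
            f"epochs={c.n_epochs} CD-{c.cd_steps} seed={c.seed}",
        ]
        if self.reconstruction_trace:
            lines.append(
                f"reconstruction error: {self.reconstruction_trace[0]:.4f} -> "
                f"{self.reconstruction_trace[-1]:.4f}"
            )
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "n_visible": self.n_visible,
            "n_hidden": self.n_hidden,
            "W": self.W.ravel().tolist(),
            "visible_bias": self.visible_bias.tolist(),
            "hidden_bias": self.hidden_bias.tolist(),
            "medication_names": self.medication_names,
            "config": vars(self.config),
            "reconstruction_trace": self.reconstruction_trace,
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MedicationRBMResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                doc = json.load(fh)
        nv, nh = doc["n_visible"], doc["n_hidden"]
        return cls(
            W=np.asarray(doc["W"], dtype=float).reshape(nv, nh),
            visible_bias=np.asarray(doc["visible_bias"], dtype=float),
            hidden_bias=np.asarray(doc["hidden_bias"], dtype=float),
            medication_names=list(doc["medication_names"]),
            config=RBMConfig(**doc["config"]),
            reconstruction_trace=list(doc["reconstruction_trace"]),
        )


@dataclass
class MedicationClusterAssignment:
    """Per-medication cluster memberships with a residual cluster.

    ``membership[name]`` is the (possibly empty) frozen set of 1-based
    hidden-unit indices the medication activates; empty membership places it
    in the residual cluster ``n_hidden + 1``.
    """

    membership: dict[str, frozenset[int]]
    n_hidden: int
    tau: float = 0.5

    def __post_init__(self) -> None:
        valid = set(range(1, self.n_hidden + 1))
        for name, mem in self.membership.items():
            if not set(mem) <= valid:
                raise ValueError(f"membership of {name!r} outside 1..{self.n_hidden}")

    @property
    def n_clusters(self) -> int:
        return self.n_hidden + 1

    @property
    def residual_index(self) -> int:
        return self.n_hidden + 1

    def effective_membership(self, name: str) -> frozenset[int]:
        """Membership with the residual cluster filled in for orphans."""
        mem = self.membership[name]
        return mem if mem else frozenset({self.residual_index})

    def cluster_members(self, k: int) -> list[str]:
        if not 1 <= k <= self.n_clusters:
            raise ValueError(f"cluster index {k} outside 1..{self.n_clusters}")
        return sorted(n for n in self.membership if k in self.effective_membership(n))

    def indicator(self, medication_names=None) -> pd.DataFrame:
        """[medications x n_clusters] 0/1 membership matrix (residual last)."""
        names = list(medication_names) if medication_names is not None else sorted(self.membership)
        M = np.zeros((len(names), self.n_clusters), dtype=float)
        for i, name in enumerate(names):
            for k in self.effective_membership(name):
                M[i, k - 1] = 1.0
        cols = [f"cluster_{k}" for k in range(1, self.n_clusters + 1)]
        return pd.DataFrame(M, index=names, columns=cols)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (name, ";".join(map(str, sorted(self.effective_membership(name)))))
            for name in sorted(self.membership)
        ]
        return pd.DataFrame(rows, columns=["medication_name", "clusters"])


# -- functional surfaces ----------------------------------------------------

def train_rbm(matrix, n_hidden: int = 5, config: RBMConfig | None = None) -> MedicationRBMResults:
    """Convenience wrapper: build a :class:`MedicationRBM` and fit it."""
    config = config or RBMConfig()
    return MedicationRBM(matrix, n_hidden=n_hidden).fit(
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        n_epochs=config.n_epochs,
        cd_steps=config.cd_steps,
        seed=config.seed,
    )


def hidden_activation(model: MedicationRBMResults, v) -> np.ndarray:
    """P(h = 1 | v); see :meth:`MedicationRBMResults.hidden_activation`."""
    return model.hidden_activation(v)


def assign_medication_clusters(model: MedicationRBMResults, tau: float = 0.5) -> MedicationClusterAssignment:
    """Assign each medication to the hidden clusters it activates.

    Medication i joins cluster k iff sigma(W[i,k] + c_k) > tau (clamping the
    one-hot visible vector e_i).  Multi-membership is allowed; medications
    activating no unit fall into the residual cluster.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie strictly in (0, 1)")
    act = expit(model.hidden_bias[None, :] + model.W)  # [n_visible, n_hidden]
    membership = {}
    for i, name in enumerate(model.medication_names):
        membership[name] = frozenset(int(k + 1) for k in np.flatnonzero(act[i] > tau))
    return MedicationClusterAssignment(membership, n_hidden=model.n_hidden, tau=tau)
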