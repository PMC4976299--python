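"""First-order linear-chain conditional random field.

The model assigns a label sequence Y to a token sequence W the conditional
probability

    p(Y | W) = exp( sum_t [ trans(y_{t-1}, y_t) + emit(x_t, y_t) ] ) / Z(W)

where ``emit(x_t, y)`` sums the weights of the binary features active at
position t under label y, ``trans`` is a full label-transition weight
matrix (first-order Markov dependence), and Z(W) normalizes over all label
sequences. Training maximizes the L2-penalized conditional log-likelihood
with a Quasi-Newton optimizer (L-BFGS-B via scipy); the gradient comes from
forward-backward marginals. Decoding is exact Viterbi. Both are
deterministic: a fixed model and input always yield the same labels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

logger = logging.getLogger(__name__)


@dataclass
class CrfModel:
    """A trained linear-chain CRF.

    ``emission`` is an (n_features, n_labels) weight matrix over the active
    binary features; ``transition`` is (n_labels+1, n_labels), row 0 holding
    start-transition weights. ``meta`` records the optimizer, regularization
    and convergence details.
    """

    labels: tuple[str, ...]
    feature_index: dict[str, int]
    emission: np.ndarray
    transition: np.ndarray
    meta: dict = field(default_factory=dict)

    # -- scoring -----------------------------------------------------------

    def _emissions(self, feats: Sequence[set[str]]) -> np.ndarray:
        fi = self.feature_index
        L = len(self.labels)
        out = np.zeros((len(feats), L))
        for t, fs in enumerate(feats):
            for f in fs:
                j = fi.get(f)
                if j is not None:
                    out[t] += self.emission[j]
        return out

    def decode(self, feats: Sequence[set[str]]) -> list[str]:
        """Viterbi-decode the most probable label sequence."""
        T = len(feats)
        if T == 0:
            return []
        L = len(self.labels)
        E = self._emissions(feats)
        trans = self.transition[1:]  # (L, L)
        delta = self.transition[0] + E[0]
        back = np.zeros((T, L), dtype=np.intp)
        for t in range(1, T):
            scores = delta[:, None] + trans  # prev x cur
            back[t] = np.argmax(scores, axis=0)
            delta = scores[back[t], np.arange(L)] + E[t]
        path = [int(np.argmax(delta))]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return [self.labels[i] for i in path]

    def sequence_log_likelihood(
        self, feats: Sequence[set[str]], labels: Sequence[str]
    ) -> float:
        """Conditional log p(labels | features) under the model."""
        T = len(feats)
        if T == 0:
            return 0.0
        lab_idx = [self.labels.index(l) for l in labels]
        E = self._emissions(feats)
        score = self.transition[0, lab_idx[0]] + E[0, lab_idx[0]]
        for t in range(1, T):
            score += self.transition[1 + lab_idx[t - 1], lab_idx[t]] + E[t, lab_idx[t]]
        # log Z via forward recursion
        alpha = self.transition[0] + E[0]
        for t in range(1, T):
            alpha = logsumexp(alpha[:, None] + self.transition[1:], axis=0) + E[t]
        return float(score - logsumexp(alpha))

    def feature_weights(self) -> dict[str, float]:
        """Max-|weight| per feature name across labels (for pruning)."""
        mags = np.abs(self.emission).max(axis=1)
        signed = self.emission[np.arange(len(mags)), np.abs(self.emission).argmax(axis=1)]
        return {f: float(signed[j]) for f, j in self.feature_index.items()}

    def prune(self, threshold: float) -> int:
        """Drop features whose max |weight| is below ``threshold``.

        Returns the number of features removed. Shrinks the model in place.
        """
        if threshold < 0:
            raise ValueError("threshold must be non-negative")
        keep_mask = np.abs(self.emission).max(axis=1) >= threshold
        old_names = sorted(self.feature_index, key=self.feature_index.get)
        kept = [name for name, k in zip(old_names, keep_mask) if k]
        self.emission = self.emission[keep_mask]
        self.feature_index = {name: j for j, name in enumerate(kept)}
        n_dropped = int((~keep_mask).sum())
        if kept == [] and n_dropped:
            logger.warning("all %d features pruned from model", n_dropped)
        return n_dropped

    # -- persistence ---------------------------------------------------------

    def to_json(self, stream: IO[str]) -> None:
        json.dump(
            {
                "format": "dislex-crf",
                "version": 1,
                "labels": list(self.labels),
                "features": sorted(self.feature_index, key=self.feature_index.get),
                "emission": self.emission.tolist(),
                "transition": self.transition.tolist(),
                "meta": self.meta,
            },
            stream,
        )

    @classmethod
    def from_json(cls, stream: IO[str]) -> "CrfModel":
        d = json.load(stream)
        if d.get("format") != "dislex-crf":
            raise ValueError("not a dislex CRF model file")
        return cls(
            labels=tuple(d["labels"]),
            feature_index={f: j for j, f in enumerate(d["features"])},
            emission=np.asarray(d["emission"], dtype=float),
            transition=np.asarray(d["transition"], dtype=float),
            meta=d.get("meta", {}),
        )


def _index_sequences(
    X: Sequence[Sequence[set[str]]],
) -> tuple[dict[str, int], list[list[np.ndarray]]]:
    feature_index: dict[str, int] = {}
    indexed: list[list[np.ndarray]] = []
    for feats in X:
        seq = []
        for fs in feats:
            ids = []
            for f in sorted(fs):
                j = feature_index.setdefault(f, len(feature_index))
                ids.append(j)
            seq.append(np.asarray(ids, dtype=np.intp))
        indexed.append(seq)
    return feature_index, indexed


def train_crf(
    X: Sequence[Sequence[set[str]]],
    y: Sequence[Sequence[str]],
    labels: Sequence[str],
    c2: float = 1.0,
    max_iter: int = 120,
    tol: float = 1e-5,
) -> CrfModel:
    """Fit CRF weights by penalized maximum conditional likelihood.

    ``X`` holds one feature-set sequence per sentence, ``y`` the gold label
    sequences. ``c2`` is the L2 penalty strength. Optimization uses
    L-BFGS-B; a non-converged run logs a warning with the iteration count.
    """
    if not X:
        raise ValueError("training corpus is empty")
    if len(X) != len(y):
        raise ValueError("X and y differ in length")
    labels = tuple(labels)
    L = len(labels)
    lab_to_i = {l: i for i, l in enumerate(labels)}
    feature_index, Xi = _index_sequences(X)
    yi = [np.asarray([lab_to_i[l] for l in seq], dtype=np.intp) for seq in y]
    F = len(feature_index)

    n_emit = F * L
    n_trans = (L + 1) * L

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return theta[:n_emit].reshape(F, L), theta[n_emit:].reshape(L + 1, L)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        W, A = unpack(theta)
        g_W = np.zeros_like(W)
        g_A = np.zeros_like(A)
        nll = 0.0
        for seq, lab in zip(Xi, yi):
            T = len(seq)
            if T == 0:
                continue
            E = np.zeros((T, L))
            for t, ids in enumerate(seq):
                if len(ids):
                    E[t] = W[ids].sum(axis=0)
            trans = A[1:]
            # forward
            alpha = np.zeros((T, L))
            alpha[0] = A[0] + E[0]
            for t in range(1, T):
                alpha[t] = logsumexp(alpha[t - 1][:, None] + trans, axis=0) + E[t]
            logZ = logsumexp(alpha[-1])
            # backward
            beta = np.zeros((T, L))
            for t in range(T - 2, -1, -1):
                beta[t] = logsumexp(trans + (E[t + 1] + beta[t + 1])[None, :], axis=1)
            # gold score
            score = A[0, lab[0]] + E[np.arange(T), lab].sum()
            if T > 1:
                score += A[1 + lab[:-1], lab[1:]].sum()
            nll += logZ - score
            # marginals
            node = np.exp(alpha + beta - logZ)  # (T, L)
            for t, ids in enumerate(seq):
                if len(ids):
                    np.add.at(g_W, ids, node[t])
                    g_W[ids, lab[t]] -= 1.0
            g_A[0] += node[0]
            g_A[0, lab[0]] -= 1.0
            for t in range(1, T):
                pair = np.exp(
                    alpha[t - 1][:, None] + trans + (E[t] + beta[t])[None, :] - logZ
                )
                g_A[1:] += pair
                g_A[1 + lab[t - 1], lab[t]] -= 1.0
        nll += c2 * float(theta @ theta)
        grad = np.concatenate([g_W.ravel(), g_A.ravel()]) + 2.0 * c2 * theta
        return nll, grad

    theta0 = np.zeros(n_emit + n_trans)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-5},
    )
    if not res.success:
        logger.warning(
            "optimizer did not converge after %d iterations: %s",
            res.nit,
            res.message,
        )
    W, A = unpack(res.x)
    return CrfModel(
        labels=labels,
        feature_index=feature_index,
        emission=W.copy(),
        transition=A.copy(),
        meta={
            "optimizer": "L-BFGS-B",
            "c2": c2,
            "iterations": int(res.nit),
            "converged": bool(res.success),
            "final_nll": float(res.fun),
        },
    )
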