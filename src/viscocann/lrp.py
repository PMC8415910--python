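"""Layer-wise relevance propagation (alpha-beta rule) for both blocks.

A trained network's scalar output is traced back to its inputs by
recursively splitting each neuron's relevance over its inputs.  With
``z_ij = w_ij x_i`` and ``z_j = sum_i z_ij + b_j``, the alpha-beta rule
propagates

    R_{i<-j} = R_j * (alpha * z_ij^+ / z_j^+  +  beta * z_ij^- / z_j^-)

where ^+/^- denote positive/negative parts (of the ``z_ij`` and of the
bias) and ``alpha + beta = 1`` (defaults alpha=2, beta=-1).  Two documented
choices close gaps the rule leaves open:

* zero-denominator guard -- when a neuron has no negative inputs
  (``z_j^- = 0``) the beta term is dropped and the alpha term renormalized
  to coefficient 1, so conservation still holds (and symmetrically for
  ``z_j^+ = 0``); without the guard the raw rule inflates relevance by
  alpha.
* bias relevance is absorbed, not redistributed to the inputs, which is
  the source of the small conservation leakage across deep stacks.

For the energy block, relevance is seeded with the block's energy output,
averaged over a fixed probe set of deformation states, and only the 11
composition features are reported (relevance landing on the invariant
inputs is discarded).  For the Prony block the four raw outputs seed the
propagation jointly (their relevances sum).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import FEATURES, PROBE_STRETCHES, ViscoCANN
from .nn import MLP

__all__ = [
    "propagate_layer",
    "network_relevance",
    "energy_block_relevance",
    "prony_block_relevance",
    "aggregate_relevance",
]

DEFAULT_ALPHA = 2.0
DEFAULT_BETA = -1.0


def propagate_layer(R_next, W, b, x_prev, *, alpha=DEFAULT_ALPHA, beta=DEFAULT_BETA):
    """Propagate relevance across one dense layer.

    Parameters
    ----------
    R_next : (n_j,) relevances of the layer's output neurons.
    W : (n_i, n_j) weights; b : (n_j,) biases.
    x_prev : (n_i,) cached activations feeding the layer (the forward
        pass must have been run on the same input).
    """
    if abs(alpha + beta - 1.0) > 1e-12:
        raise ValueError(f"alpha + beta must equal 1; got alpha={alpha}, beta={beta}")
    R_next = np.asarray(R_next, float)
    W = np.asarray(W, float)
    b = np.asarray(b, float)
    x_prev = np.asarray(x_prev, float)
    z = x_prev[:, None] * W
    pos = np.maximum(z, 0.0)
    neg = np.minimum(z, 0.0)
    zp = pos.sum(axis=0) + np.maximum(b, 0.0)
    zn = neg.sum(axis=0) + np.minimum(b, 0.0)
    has_pos = zp > 0.0
    has_neg = zn < 0.0
    both = has_pos & has_neg
    w_pos = np.where(both, alpha, np.where(has_pos, 1.0, 0.0))
    w_neg = np.where(both, beta, np.where(has_neg, 1.0, 0.0))
    zp_safe = np.where(has_pos, zp, 1.0)
    zn_safe = np.where(has_neg, zn, 1.0)
    return pos @ (R_next * w_pos / zp_safe) + neg @ (R_next * w_neg / zn_safe)


def network_relevance(mlp: MLP, x_input, R_out, *, alpha=DEFAULT_ALPHA, beta=DEFAULT_BETA):
    """Recursively propagate output relevances to the input layer."""
    xs, _ = mlp.forward(np.atleast_2d(x_input))
    R = np.asarray(R_out, float)
    for l in range(mlp.n_layers - 1, -1, -1):
        R = propagate_layer(R, mlp.W[l], mlp.b[l], xs[l][0], alpha=alpha, beta=beta)
    return R


def energy_block_relevance(
    model: ViscoCANN, comp, *, probe_stretches=PROBE_STRETCHES,
    alpha=DEFAULT_ALPHA, beta=DEFAULT_BETA,
) -> np.ndarray:
    """Per-feature relevance of the 11 composition inputs for the energy.

    The output-layer relevance is seeded with the energy value itself and
    propagated back at each probe deformation state; results are averaged
    over the probe set and the invariant inputs' share is discarded.
    """
    if model.scaler.xbar is None:
        raise RuntimeError("relevance analysis requires a trained model with a fitted scaler")
    z = model.scale_composition(comp)
    rel = np.zeros(len(FEATURES))
    for lam in probe_stretches:
        X = model.energy_inputs(np.array([lam]), z)
        psi = model.energy_net(X)[0, 0]
        R_in = network_relevance(model.energy_net, X, np.array([psi]), alpha=alpha, beta=beta)
        rel += R_in[2:]
    return rel / len(probe_stretches)


def prony_block_relevance(
    model: ViscoCANN, comp, *, outputs: str = "all",
    alpha=DEFAULT_ALPHA, beta=DEFAULT_BETA,
) -> np.ndarray:
    """Per-feature relevance for the Prony block, summed over raw outputs.

    ``outputs="all"`` seeds every raw head with its value; ``"weights"``
    seeds only the two weight heads (g1, g2), zeroing the relaxation-time
    heads.  The latter targets claims about the Prony *weights*
    specifically: the time heads are weakly constrained by cyclic data,
    so their learned feature-dependence contributes attribution noise.
    """
    if model.scaler.xbar is None:
        raise RuntimeError("relevance analysis requires a trained model with a fitted scaler")
    if outputs not in ("all", "weights"):
        raise ValueError(f"outputs must be 'all' or 'weights', got {outputs!r}")
    z = model.scale_composition(comp)
    raw = model.prony_net(z[None, :])[0]
    seed = raw if outputs == "all" else np.array([raw[0], raw[1], 0.0, 0.0])
    return network_relevance(model.prony_net, z[None, :], seed, alpha=alpha, beta=beta)


def _normalized(rel: np.ndarray) -> np.ndarray | None:
    """Per-sample relevance magnitudes, normalized to mean 1.

    The alpha-beta rule yields signed relevances; a feature whose
    contributions flip sign across deformation states would average toward
    zero, and normalizing signed values by their (possibly tiny) mean is
    numerically unstable.  Aggregation therefore uses magnitudes, scaled
    so each sample's 11 scores average to 1 -- the O(1) scale on which
    such relevance profiles are reported.
    """
    m = np.abs(rel).mean()
    if m < 1e-12:
        return None
    return np.abs(rel) / m


def aggregate_relevance(
    fold_results, specimens, *, r2_threshold: float = 0.7,
    prony_outputs: str = "all",
    alpha=DEFAULT_ALPHA, beta=DEFAULT_BETA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled and per-region relevance tables over reliable folds.

    Only folds whose validation R^2 reaches ``r2_threshold`` contribute
    (model-accuracy filter).  Within each contributing fold, the relevance
    of every *training* specimen is computed for both blocks, each
    sample's 11 relevances are normalized to mean 1, and the normalized
    scores are averaged -- overall for the pooled table, and within
    anatomical regions for the regional table.

    Returns
    -------
    (pooled, regional) : DataFrames with columns
        ``block, feature, mean_relevance, n_samples`` and
        ``block, region, feature, mean_relevance, n_samples``.
    """
    by_id = {sp.specimen_id: sp for sp in specimens}
    rows = []
    n_pass = 0
    for f in fold_results:
        if f.failed or not np.isfinite(f.r2_val) or f.r2_val < r2_threshold:
            continue
        n_pass += 1
        for sid in f.r2_train:
            sp = by_id[sid]
            for block, fn in (
                ("energy", lambda m, c, **kw: energy_block_relevance(m, c, **kw)),
                ("prony", lambda m, c, **kw: prony_block_relevance(m, c, outputs=prony_outputs, **kw)),
            ):
                rel = _normalized(fn(f.model, sp.composition, alpha=alpha, beta=beta))
                if rel is None:
                    warnings.warn(
                        f"near-zero mean relevance for specimen {sid!r} ({block} block); sample skipped"
                    )
                    continue
                for feat, r in zip(FEATURES, rel):
                    rows.append(
                        {"block": block, "region": sp.region, "feature": feat, "relevance": r}
                    )
    cols_pooled = ["block", "feature", "mean_relevance", "n_samples"]
    cols_regional = ["block", "region", "feature", "mean_relevance", "n_samples"]
    if not rows:
        warnings.warn(
            f"no folds passed the validation R^2 >= {r2_threshold} filter; relevance tables are empty"
        )
        return pd.DataFrame(columns=cols_pooled), pd.DataFrame(columns=cols_regional)
    df = pd.DataFrame(rows)
    pooled = (
        df.groupby(["block", "feature"], sort=False)["relevance"]
        .agg(mean_relevance="mean", n_samples="size")
        .reset_index()
    )
    regional = (
        df.groupby(["block", "region", "feature"], sort=False)["relevance"]
        .agg(mean_relevance="mean", n_samples="size")
        .reset_index()
    )
    return pooled[cols_pooled], regional[cols_regional]
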