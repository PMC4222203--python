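"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np

from oceansdm.occurrences import SampleMatrix


def make_matrix(X, variables, role="presence") -> SampleMatrix:
    """Wrap a raw covariate array in a SampleMatrix with dummy cell ids."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    return SampleMatrix(
        X=X,
        variables=tuple(variables),
        role=role,
        cell_ids=[(0, i) for i in range(n)],
        months=np.zeros(n, dtype=int),
    )


def grid_search_objective(Fp, Fb, betas, box=10.0, levels=(1.0, 0.1, 0.01, 0.001)):
    """Independent brute-force minimizer of the penalized maxent objective.

    Exhaustive grid search over [-box, box]^d, refined around the incumbent
    at successively finer steps. Evaluates the objective directly from its
    definition (no shared code with the fitter's update rules).
    """
    from scipy.special import logsumexp

    d = Fp.shape[1]
    pbar = Fp.mean(axis=0)

    def evaluate(grid_pts):
        eta = grid_pts @ Fb.T  # (G, N)
        return (
            -grid_pts @ pbar
            + logsumexp(eta, axis=1)
            + np.abs(grid_pts) @ betas
        )

    center = np.zeros(d)
    half = box
    best_val = None
    best_pt = center
    for step in levels:
        axes = [
            np.arange(center[k] - half, center[k] + half + step / 2, step)
            for k in range(d)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        vals = evaluate(pts)
        i = int(np.argmin(vals))
        best_val, best_pt = float(vals[i]), pts[i]
        center, half = best_pt, step
    return best_val, best_pt
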