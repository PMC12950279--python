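"""Independent brute-force oracles used to cross-check closed-form code.

These deliberately avoid the package's own computational paths: grid
integration for Bayesian moments, explicit block-matrix GLS, hand-assembled
Efron partial likelihood, and exhaustive pair counting for AUC.
"""

import numpy as np
from scipy import stats


def grid_posterior_moments(times, y, beta, sigma_b, sigma2,
                           t_query=None, n=321, span=9.0):
    """Posterior/predictive moments by 2D Riemann integration.

    Prior (b0, b1) ~ N(0, sigma_b); likelihood y_j ~ N(x_j (beta + b),
    sigma2). Returns (post_mean, post_cov[, pred_mean, pred_sd]).
    """
    s0, s1 = np.sqrt(sigma_b[0, 0]), np.sqrt(sigma_b[1, 1])
    g0 = np.linspace(-span * s0, span * s0, n)
    g1 = np.linspace(-span * s1, span * s1, n)
    B0, B1 = np.meshgrid(g0, g1, indexing="ij")
    pts = np.stack([B0.ravel(), B1.ravel()], axis=1)

    logp = stats.multivariate_normal(mean=[0, 0], cov=sigma_b).logpdf(pts)
    for t_j, y_j in zip(times, y):
        mu = (beta[0] + pts[:, 0]) + (beta[1] + pts[:, 1]) * t_j
        logp += stats.norm.logpdf(y_j, mu, np.sqrt(sigma2))
    w = np.exp(logp - logp.max())
    w /= w.sum()

    mean = w @ pts
    centered = pts - mean
    cov = (centered * w[:, None]).T @ centered
    if t_query is None:
        return mean, cov
    x = np.array([1.0, t_query])
    vals = (beta[0] + pts[:, 0]) + (beta[1] + pts[:, 1]) * t_query
    pred_mean = w @ vals
    pred_var = w @ (vals - pred_mean) ** 2 + sigma2
    return mean, cov, pred_mean, np.sqrt(pred_var)


def block_gls(times_by_subject, y_by_subject, sigma_b, sigma2):
    """Fixed effects from one explicit stacked GLS solve."""
    blocks, Xs, ys = [], [], []
    for t_i, y_i in zip(times_by_subject, y_by_subject):
        X = np.column_stack([np.ones(len(t_i)), np.asarray(t_i)])
        blocks.append(X @ sigma_b @ X.T + sigma2 * np.eye(len(t_i)))
        Xs.append(X)
        ys.append(np.asarray(y_i))
    from scipy.linalg import block_diag
    V = block_diag(*blocks)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    Vinv = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)


def efron_loglik(df, beta_grid, cov="z"):
    """Efron-tie-corrected Cox partial log-likelihood on a beta grid.

    ``df`` holds counting-process rows (start, stop, event, covariate);
    risk set at event time te is {rows: start < te <= stop}.
    """
    beta_grid = np.atleast_1d(np.asarray(beta_grid, dtype=float))
    x = df[cov].to_numpy(dtype=float)
    start = df["start"].to_numpy(dtype=float)
    stop = df["stop"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=bool)
    E = np.exp(np.outer(x, beta_grid))  # (rows, n_beta)
    ll = np.zeros(beta_grid.shape)
    for te in np.unique(stop[event]):
        at_risk = (start < te) & (te <= stop)
        died = event & (stop == te)
        d = int(died.sum())
        risk_sum = E[at_risk].sum(axis=0)
        died_sum = E[died].sum(axis=0)
        ll += x[died].sum() * beta_grid
        for ell in range(d):
            ll -= np.log(risk_sum - (ell / d) * died_sum)
    return ll


def pair_count_auc(scores, labels):
    """AUC by exhaustive positive-negative pair counting (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
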