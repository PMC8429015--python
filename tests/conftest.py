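import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_symmetric_affinity(rng, n):
    """Random valid affinity: symmetric, zero-diagonal, weights in [0, 1]."""
    W = rng.uniform(0.0, 1.0, size=(n, n))
    W = np.triu(W, 1)
    W = W + W.T
    # sparsify a little so some pairs are non-neighbours
    mask = rng.uniform(size=(n, n)) < 0.4
    mask = np.triu(mask, 1)
    W[mask | mask.T] = 0.0
    return W


def random_problem(rng, d=None, n=None, c=2):
    """A small random instance of the joint-projection problem."""
    from mvbiomarkers.graphs import AffinityGraph, build_laplacian
    from mvbiomarkers.projection import HyperParams, LabelIndicator, ViewPair

    d = int(rng.integers(3, 9)) if d is None else d
    n = int(rng.integers(6, 16)) if n is None else n
    Xct = rng.normal(size=(d, n))
    Xcv = rng.normal(size=(d, n))
    views = ViewPair(X_CT=Xct, X_CV=Xcv)
    codes = rng.integers(0, c, size=n)
    codes[:c] = np.arange(c)  # both classes present
    Y = np.zeros((n, c))
    Y[np.arange(n), codes] = 1.0
    lab = LabelIndicator(Y=Y, class_order=tuple(f"class{j}" for j in range(c)))
    W_ct = random_symmetric_affinity(rng, n)
    W_cv = random_symmetric_affinity(rng, n)
    L_ct = build_laplacian(AffinityGraph(W=W_ct, k=0, sigma=1.0))
    L_cv = build_laplacian(AffinityGraph(W=W_cv, k=0, sigma=1.0))
    hp = HyperParams(
        lam=float(rng.uniform(0.1, 0.9)),
        alpha=float(10.0 ** rng.uniform(-3, 1)),
        beta=float(10.0 ** rng.uniform(-1, 1)),
    )
    return views, lab, L_ct, L_cv, hp, (W_ct, W_cv)


def objective_loops(U, V, Xct, Xcv, Y, W_ct, W_cv, lam, alpha, beta):
    """Independent scalar-loop evaluation of the four objective terms.

    Uses only Python loops and the affinity matrices (the graph term is
    the pairwise half-sum, never the Laplacian trace form).
    """
    d, n = Xct.shape
    c = Y.shape[1]
    A = [[sum(Xct[f, i] * U[f, j] for f in range(d)) for j in range(c)] for i in range(n)]
    B = [[sum(Xcv[f, i] * V[f, j] for f in range(d)) for j in range(c)] for i in range(n)]
    label = sum((Y[i, j] - A[i][j]) ** 2 for i in range(n) for j in range(c))
    label += sum((Y[i, j] - B[i][j]) ** 2 for i in range(n) for j in range(c))
    cross = sum((A[i][j] - B[i][j]) ** 2 for i in range(n) for j in range(c))
    graph = 0.0
    for i in range(n):
        for j in range(n):
            graph += 0.5 * W_ct[i, j] * sum((A[i][t] - A[j][t]) ** 2 for t in range(c))
            graph += 0.5 * W_cv[i, j] * sum((B[i][t] - B[j][t]) ** 2 for t in range(c))
    ridge = sum(U[f, j] ** 2 for f in range(d) for j in range(c))
    ridge += sum(V[f, j] ** 2 for f in range(d) for j in range(c))
    return lam * label + (1 - lam) * cross + alpha * graph + beta * ridge
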