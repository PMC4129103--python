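"""Synthetic data generator and type-I-error / power experiment harness.

The generative model is a multivariate linear design: the gene block
``X (n x p)`` is multivariate normal with exchangeable correlation ``rho``,
and the phenotype block is

    Y = X @ beta + eps,

with ``eps (n x q)`` multivariate normal, also with exchangeable correlation
``rho`` so that phenotype pairs are correlated.  Under the null every entry
of ``beta`` is 0; under the alternative a randomly chosen 5 x 3 block of
``beta`` (5 gene rows, 3 phenotype columns) is set to a common effect ``mu``,
so exactly 15 entries carry signal and the gene-phenotype correlation grows
with ``mu``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lct import lct_test
from .nlct import nlct_test
from .shrinkage import center_scale

__all__ = [
    "SimulationConfig",
    "ExperimentResult",
    "exchangeable_mvn",
    "make_coefficients",
    "simulate_dataset",
    "type1_experiment",
    "power_experiment",
    "scaled",
]

#: Alternative-model signal block: 5 gene rows x 3 phenotype columns.
SIGNAL_ROWS = 5
SIGNAL_COLS = 3


@dataclass
class SimulationConfig:
    """One simulation cell (or the shared settings of a mu-grid).

    ``n_replicates`` and ``n_perm`` default to the scaled-down profile used
    by the test suite; the full-scale study uses 1000 replicates and 1000
    permutations per test.
    """

    n: int = 20
    p: int = 20
    q: int = 10
    rho: float = 0.0
    n_replicates: int = 200
    n_perm: int = 200
    alpha: float = 0.05
    seed: int = 0
    method: str = "lct"
    df: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.n < 3:
            raise ValueError("n must be at least 3")
        if self.method not in ("lct", "nlct"):
            raise ValueError("method must be 'lct' or 'nlct'")


@dataclass
class ExperimentResult:
    """Rejection rates with Monte-Carlo standard errors, one row per cell."""

    cells: list[dict] = field(default_factory=list)
    grid: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = ["method", "n", "p", "q", "rho", "mu", "replicates", "perms",
                "rejection_rate", "mc_se"]
        return pd.DataFrame(self.cells, columns=cols)


def exchangeable_mvn(
    n: int, m: int, rho: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n x m`` zero-mean, unit-variance normals with common pairwise
    correlation ``rho``, via a shared factor: ``sqrt(rho) * z0 + sqrt(1-rho) * z``.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shared = rng.standard_normal((n, 1))
    idio = rng.standard_normal((n, m))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * idio


def make_coefficients(
    p: int, q: int, mu: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """The ``p x q`` coefficient matrix of the generative model.

    ``mu = 0`` gives the all-zero null matrix.  For ``mu > 0``, 5 rows and 3
    columns are drawn without replacement and the 15 entries at their
    intersection are set to ``mu``.
    """
    beta = np.zeros((p, q))
    if mu == 0:
        return beta
    if p < SIGNAL_ROWS or q < SIGNAL_COLS:
        raise ValueError(
            f"alternative model needs p >= {SIGNAL_ROWS} and q >= {SIGNAL_COLS}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = rng.choice(p, SIGNAL_ROWS, replace=False)
    cols = rng.choice(q, SIGNAL_COLS, replace=False)
    beta[np.ix_(rows, cols)] = mu
    return beta


def simulate_dataset(
    cfg: SimulationConfig, mu: float, replicate_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One raw ``(X, Y)`` draw from the generative model for a replicate."""
    child = np.random.SeedSequence(replicate_seed).spawn(3)
    X = exchangeable_mvn(cfg.n, cfg.p, cfg.rho, np.random.default_rng(child[0]))
    eps = exchangeable_mvn(cfg.n, cfg.q, cfg.rho, np.random.default_rng(child[1]))
    beta = make_coefficients(cfg.p, cfg.q, mu, np.random.default_rng(child[2]))
    return X, X @ beta + eps


def _rejection_rate(cfg: SimulationConfig, mu: float, cell_key: int) -> tuple[float, float]:
    """Fraction of replicates with p <= alpha, plus its binomial MC SE."""
    root = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(cell_key,))
    rejected = 0
    for rep, child in enumerate(root.spawn(cfg.n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        X_raw, Y_raw = simulate_dataset(cfg, mu, rep_seed)
        X = center_scale(X_raw)
        Y = center_scale(Y_raw)
        perm_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=rep_seed, spawn_key=(1,))
        )
        if cfg.method == "lct":
            res = lct_test(X, Y, n_perm=cfg.n_perm, seed=perm_rng)
        else:
            res = nlct_test(X, Y, df=cfg.df, n_perm=cfg.n_perm, seed=perm_rng)
        if res.p_value <= cfg.alpha:
            rejected += 1
    rate = rejected / cfg.n_replicates
    return rate, float(np.sqrt(rate * (1.0 - rate) / cfg.n_replicates))


def _cell_record(cfg: SimulationConfig, mu: float, rate: float, se: float) -> dict:
    return {
        "method": cfg.method, "n": cfg.n, "p": cfg.p, "q": cfg.q, "rho": cfg.rho,
        "mu": mu, "replicates": cfg.n_replicates, "perms": cfg.n_perm,
        "rejection_rate": rate, "mc_se": se,
    }


def type1_experiment(cfg: SimulationConfig) -> ExperimentResult:
    """Null-model (``mu = 0``) rejection rate at level ``alpha``."""
    rate, se = _rejection_rate(cfg, mu=0.0, cell_key=0)
    return ExperimentResult(cells=[_cell_record(cfg, 0.0, rate, se)], grid=[0.0])


def power_experiment(cfg: SimulationConfig, mu_grid: list[float]) -> ExperimentResult:
    """Rejection rate along a grid of effect sizes ``mu`` (``mu = 0`` cell is
    the type-I error)."""
    if any(mu < 0 for mu in mu_grid):
        raise ValueError("mu values must be nonnegative")
    result = ExperimentResult(grid=list(mu_grid))
    for k, mu in enumerate(mu_grid):
        rate, se = _rejection_rate(cfg, mu=float(mu), cell_key=k)
        result.cells.append(_cell_record(cfg, float(mu), rate, se))
    return result


def make_gsa_fixture(
    n: int = 50,
    p: int = 10,
    q: int = 5,
    rho: float = 0.3,
    mu: float = 3.0,
    n_sets: int = 20,
    seed: int = 0,
):
    """A complete synthetic GSA study: one truly associated set among decoys.

    Each of ``n_sets`` gene sets gets its own ``p`` genes drawn with
    exchangeable correlation ``rho``; one randomly chosen set drives the
    phenotypes through the 15-entry ``mu`` block, the rest are pure noise.

    Returns
    -------
    (expression, phenotypes, sets, planted_name)
        ``expression`` is a subjects x genes frame, ``phenotypes`` a subjects
        x q frame, ``sets`` a list of :class:`~lctgsa.gsa.GeneSet`.
    """
    from .gsa import GeneSet

    rng = np.random.default_rng(seed)
    planted = int(rng.integers(n_sets))
    blocks, sets = [], []
    gene_names: list[str] = []
    for i in range(n_sets):
        names = [f"G{i * p + j + 1:04d}" for j in range(p)]
        gene_names.extend(names)
        sets.append(GeneSet(name=f"SET{i + 1:02d}", description="synthetic", genes=names))
        blocks.append(exchangeable_mvn(n, p, rho, rng))
    beta = make_coefficients(p, q, mu, rng)
    eps = exchangeable_mvn(n, q, rho, rng)
    Y = blocks[planted] @ beta + eps
    samples = [f"S{i + 1:03d}" for i in range(n)]
    expression = pd.DataFrame(np.hstack(blocks), index=samples, columns=gene_names)
    phenotypes = pd.DataFrame(Y, index=samples, columns=[f"pheno{j + 1}" for j in range(q)])
    return expression, phenotypes, sets, sets[planted].name


def scaled(cfg: SimulationConfig, profile: str) -> SimulationConfig:
    """Return a copy of ``cfg`` at the requested profile: ``full`` is the
    1000-replicate / 1000-permutation study design, ``reduced`` the 200/200
    profile used for quick runs."""
    if profile == "full":
        return replace(cfg, n_replicates=1000, n_perm=1000)
    if profile == "reduced":
        return replace(cfg, n_replicates=200, n_perm=200)
    raise ValueError("profile must be 'full' or 'reduced'")
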