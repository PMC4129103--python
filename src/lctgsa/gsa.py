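"""Gene-set I/O, multi-set GSA execution, and FDR reporting.

Reads GMT gene-set collections (MSigDB dialect) and delimited expression /
phenotype matrices, runs LCT or NLCT per gene set with a set-specific
deterministic seed, and attaches a Benjamini-Hochberg FDR column across all
tested sets.  Sets whose intersection with the measured-gene universe falls
outside the configured size range (default 5-500) are dropped before
testing, mirroring standard self-contained GSA practice.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lct import lct_test
from .nlct import nlct_test
from .shrinkage import center_scale

__all__ = [
    "GeneSet",
    "read_gmt",
    "read_matrix",
    "write_matrix",
    "filter_genesets",
    "bh_fdr",
    "storey_qvalues",
    "run_gsa",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 500


@dataclass
class GeneSet:
    """A named gene set: unique member identifiers plus a free-text description."""

    name: str
    description: str = ""
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be nonempty")
        seen = set()
        unique = []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                unique.append(g)
        self.genes = unique

    @property
    def size(self) -> int:
        return len(self.genes)


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: tab-delimited ``name<TAB>description<TAB>gene...``.

    Duplicate genes within a line are deduplicated with a warning; a line
    with fewer than three fields raises with its line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if len(genes) != len(set(genes)):
                logger.warning("%s: line %d: duplicate genes in set %s deduplicated",
                               path, lineno, name)
            sets.append(GeneSet(name=name, description=desc, genes=genes))
    return sets


def read_matrix(path, orientation: str = "samples-in-rows") -> pd.DataFrame:
    """Read a labeled TSV/CSV matrix into the internal subjects x variables form.

    ``orientation='genes-in-rows'`` (the expression-file convention) is
    transposed on read; ``'samples-in-rows'`` (the phenotype convention) is
    kept as is.  Non-numeric cells and duplicate row/column identifiers are
    errors.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError("orientation must be 'genes-in-rows' or 'samples-in-rows'")
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row identifiers: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column identifiers: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise ValueError(f"{path}: non-numeric value at row {r!r}, column {c!r}")
    if numeric.isna().any().any():
        r = numeric.isna().any(axis=1).idxmax()
        raise ValueError(f"{path}: missing value in row {r!r}")
    if orientation == "genes-in-rows":
        numeric = numeric.T
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return numeric


def write_matrix(df: pd.DataFrame, path, orientation: str = "samples-in-rows") -> None:
    """Write a subjects x variables matrix back to TSV (inverse of read)."""
    out = df.T if orientation == "genes-in-rows" else df
    sep = "," if str(path).endswith(".csv") else "\t"
    out.to_csv(path, sep=sep)


def filter_genesets(
    sets: list[GeneSet],
    universe: list[str],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> list[GeneSet]:
    """Intersect each set with the measured-gene universe and keep those whose
    *matched* size lies in ``[min_size, max_size]``."""
    if min_size < 1:
        raise ValueError("min_size must be at least 1")
    known = set(universe)
    kept = []
    for s in sets:
        matched = [g for g in s.genes if g in known]
        if min_size <= len(matched) <= max_size:
            kept.append(GeneSet(name=s.name, description=s.description, genes=matched))
    return kept


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalues(p_values, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-point pi0 estimate at ``lam``.

    ``pi0 = min(1, #{p > lam} / ((1 - lam) m))``; q-values are ``pi0`` times
    the BH adjustment.  Offered as an alternative to :func:`bh_fdr`.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam))
    pi0 = max(pi0, 1.0 / p.size)  # guard against pi0 = 0 on tiny inputs
    return np.minimum(pi0 * bh_fdr(p), 1.0)


def _set_seed(master_seed: int, set_name: str) -> int:
    """Deterministic per-set seed, independent of set ordering."""
    return int(
        np.random.SeedSequence(
            entropy=master_seed, spawn_key=(zlib.crc32(set_name.encode()),)
        ).generate_state(1)[0]
        % 2**31
    )


def run_gsa(
    expression: pd.DataFrame,
    phenotypes: pd.DataFrame,
    sets: list[GeneSet],
    method: str = "lct",
    n_perm: int = 1000,
    seed: int = 0,
    df: int = 5,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Test every gene set for association with the phenotype block.

    Parameters
    ----------
    expression, phenotypes
        Subjects x variables frames (as returned by :func:`read_matrix`)
        sharing the same sample identifiers.
    sets
        Gene sets, normally pre-filtered with :func:`filter_genesets`.
    method
        ``'lct'`` or ``'nlct'`` (the latter with spline ``df``).
    n_perm, seed
        Permutation count and master seed; each set derives its own seed
        from ``(seed, hash(set name))`` so results do not depend on set
        order or on which other sets are present.

    Returns
    -------
    pandas.DataFrame
        Columns ``set, size, matched, statistic, p_value, fdr, status``.
        Sets with fewer than 2 usable genes are flagged untested and
        excluded from the FDR adjustment.
    """
    if method not in ("lct", "nlct"):
        raise ValueError("method must be 'lct' or 'nlct'")
    if fdr_method not in ("bh", "storey"):
        raise ValueError("fdr_method must be 'bh' or 'storey'")
    missing = [s for s in expression.index if s not in set(phenotypes.index)]
    if missing or len(expression.index) != len(phenotypes.index):
        raise ValueError("expression and phenotypes must share the same samples")
    phenotypes = phenotypes.loc[expression.index]
    Y = center_scale(phenotypes.to_numpy(), list(phenotypes.columns))
    measured = set(expression.columns)
    rows = []
    for s in sets:
        matched = [g for g in s.genes if g in measured]
        sub = expression[matched].to_numpy() if matched else np.empty((len(expression), 0))
        usable = [g for g, sd in zip(matched, sub.std(axis=0, ddof=1)) if sd > 0] if matched else []
        if len(usable) < len(matched):
            logger.warning("set %s: dropped %d zero-variance gene(s)",
                           s.name, len(matched) - len(usable))
        record = {"set": s.name, "size": s.size, "matched": len(matched),
                  "statistic": np.nan, "p_value": np.nan, "fdr": np.nan}
        if len(usable) < 2:
            record["status"] = "untested:fewer_than_2_usable_genes"
        else:
            X = center_scale(expression[usable].to_numpy(), usable)
            set_seed = _set_seed(seed, s.name)
            if method == "lct":
                res = lct_test(X, Y, n_perm=n_perm, seed=set_seed)
            else:
                res = nlct_test(X, Y, df=df, n_perm=n_perm, seed=set_seed)
            record.update(statistic=res.statistic, p_value=res.p_value, status="tested")
        rows.append(record)
    table = pd.DataFrame(rows, columns=["set", "size", "matched", "statistic",
                                        "p_value", "fdr", "status"])
    tested = table["status"] == "tested"
    if tested.any():
        adjust = bh_fdr if fdr_method == "bh" else storey_qvalues
        table.loc[tested, "fdr"] = adjust(table.loc[tested, "p_value"].to_numpy())
    return table
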