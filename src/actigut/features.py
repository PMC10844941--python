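"""Diversity metrics, Bray-Curtis dissimilarity and functional-module scoring.

Alpha diversity (Shannon, inverse Simpson, richness) is computed on counts
rarefied to a common depth; Bray-Curtis on relative abundances.  Functional
modules (e.g. gut metabolic modules, microbiota-gut-brain modules) are
defined as an ordered list of reaction steps, each a set of alternative
ortholog identifiers, and scored per sample as the median abundance over
covered steps, subject to a minimum coverage (default 2/3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DomainError, InsufficientDataError

__all__ = [
    "ModuleDefinition",
    "rarefy",
    "alpha_diversity",
    "alpha_diversity_table",
    "bray_curtis",
    "score_modules",
    "read_module_definitions",
    "write_module_definitions",
]

#: Default rarefaction depth (read pairs) used by the study protocol.
DEFAULT_RAREFACTION_DEPTH = 210_430

COVERAGE_TOL = 1e-9


@dataclass(frozen=True)
class ModuleDefinition:
    """A stepwise functional module: ordered steps of alternative orthologs."""

    module_id: str
    name: str
    steps: tuple[frozenset[str], ...]
    coverage_threshold: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if not self.steps or any(len(s) == 0 for s in self.steps):
            raise ValueError("module must have >=1 non-empty step")
        if not (0.0 < self.coverage_threshold <= 1.0):
            raise ValueError("coverage threshold must be in (0, 1]")


def rarefy(
    counts: pd.DataFrame, depth: int = DEFAULT_RAREFACTION_DEPTH, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subsample each sample's counts to a common depth without replacement.

    Uses the multivariate hypergeometric distribution (exact uniform
    subsampling of reads).  Samples whose total is below ``depth`` are
    excluded and reported.

    Returns (rarefied counts, report) where the report has one row per
    sample with its total and an ``included`` flag.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = counts.to_numpy()
    if np.any(x < 0):
        raise DomainError("counts must be non-negative")
    totals = x.sum(axis=1)
    included = totals >= depth
    out = np.zeros((int(included.sum()), x.shape[1]), dtype=np.int64)
    for i, row in enumerate(x[included].astype(np.int64)):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    rarefied = pd.DataFrame(out, index=counts.index[included], columns=counts.columns)
    report = pd.DataFrame({"total": totals, "included": included}, index=counts.index)
    return rarefied, report


def alpha_diversity(counts: np.ndarray | pd.Series) -> tuple[float, float, int]:
    """Shannon entropy (nats), inverse Simpson index and richness of one sample."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise DomainError("sample has no counts")
    p = c[c > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    inv_simpson = float(1.0 / (p**2).sum())
    return shannon, inv_simpson, int((c > 0).sum())


def alpha_diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha diversity metrics for a samples x species count table."""
    rows = [alpha_diversity(counts.iloc[i].to_numpy()) for i in range(len(counts))]
    return pd.DataFrame(rows, index=counts.index, columns=["shannon", "inv_simpson", "richness"])


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Square Bray-Curtis dissimilarity matrix between sample rows.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i).  Pairs of all-zero samples
    have an undefined dissimilarity and raise.
    """
    x = table.to_numpy(dtype=float)
    if np.any(x < 0):
        raise DomainError("abundances must be non-negative")
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 samples")
    if np.any(x.sum(axis=1) == 0):
        raise DomainError("all-zero sample: Bray-Curtis undefined")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def score_modules(
    gene_table: pd.DataFrame, definitions: list[ModuleDefinition]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify module abundances from a samples x ortholog abundance table.

    Per sample and module: each step's abundance is the sum over its
    alternative orthologs (missing identifiers contribute 0); coverage is
    the fraction of steps with positive abundance; if coverage meets the
    module's threshold, the module abundance is the median step abundance
    over *covered* steps, else 0 (absent).

    Returns (module abundance table, report).  The report flags modules
    with no resolvable ortholog at all.
    """
    n = len(gene_table)
    cols = set(gene_table.columns)
    out = np.zeros((n, len(definitions)))
    report_rows = []
    for j, mod in enumerate(definitions):
        step_abund = np.zeros((n, len(mod.steps)))
        resolvable = 0
        for k, step in enumerate(mod.steps):
            present = [o for o in step if o in cols]
            resolvable += len(present)
            if present:
                step_abund[:, k] = gene_table[present].to_numpy(dtype=float).sum(axis=1)
        covered = step_abund > 0
        coverage = covered.mean(axis=1)
        ok = coverage >= mod.coverage_threshold - COVERAGE_TOL
        for i in np.flatnonzero(ok):
            out[i, j] = np.median(step_abund[i, covered[i]])
        report_rows.append(
            {"module_id": mod.module_id, "n_steps": len(mod.steps),
             "resolvable_orthologs": resolvable, "unresolvable": resolvable == 0,
             "n_samples_present": int(ok.sum())}
        )
    table = pd.DataFrame(out, index=gene_table.index,
                         columns=[m.module_id for m in definitions])
    return table, pd.DataFrame(report_rows).set_index("module_id")


def read_module_definitions(path) -> list[ModuleDefinition]:
    """Read module definitions from the block text format.

    One module per block, blocks separated by blank lines::

        MOD001<TAB>butyrate synthesis
        K00001,K00002
        K00003
    """
    defs: list[ModuleDefinition] = []
    with open(path) as fh:
        block: list[str] = []
        for line in list(fh) + [""]:
            line = line.rstrip("\n")
            if line.strip():
                block.append(line)
                continue
            if not block:
                continue
            header = block[0].split("\t")
            if len(header) != 2:
                raise ValueError(f"malformed module header: {block[0]!r}")
            steps = tuple(
                frozenset(tok.strip() for tok in row.split(",") if tok.strip())
                for row in block[1:]
            )
            defs.append(ModuleDefinition(header[0], header[1], steps))
            block = []
    return defs


def write_module_definitions(defs: list[ModuleDefinition], path) -> None:
    with open(path, "w") as fh:
        for mod in defs:
            fh.write(f"{mod.module_id}\t{mod.name}\n")
            for step in mod.steps:
                fh.write(",".join(sorted(step)) + "\n")
            fh.write("\n")
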