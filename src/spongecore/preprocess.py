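"""Rarefaction, relative-abundance conversion and rank aggregation.

Rarefaction subsamples each sample's reads *without replacement* to a common
depth (a multivariate-hypergeometric draw per sample), which removes
sampling-effort differences before occurrence-based core extraction.  The
draw is seeded and a :class:`RarefactionLog` records the depth, seed and any
dropped samples so a run can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import CountTable, TaxonomyTable

__all__ = ["RarefactionLog", "rarefy", "to_relative_abundance", "aggregate_taxa"]

#: Depth used by the reference workflow this package reimplements.
DEFAULT_RAREFACTION_DEPTH = 41_000


@dataclass
class RarefactionLog:
    depth: int
    seed: int
    dropped_samples: list[str] = field(default_factory=list)


def rarefy(
    table: CountTable,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int = 0,
    drop_below: bool = True,
) -> tuple[CountTable, RarefactionLog]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (default) or
    raise an error with ``drop_below=False``.  A sample whose total equals
    ``depth`` is returned unchanged.
    """
    if depth < 1:
        raise ValueError("depth must be a positive integer")
    rng = np.random.default_rng(seed)
    sums = table.row_sums()
    below = list(sums.index[sums < depth])
    if below and not drop_below:
        raise ValueError(f"sample(s) below rarefaction depth {depth}: {below}")
    keep = [s for s in table.sample_ids if s not in set(below)]
    if not keep:
        raise ValueError(f"all samples are below the rarefaction depth {depth}")
    out = np.empty((len(keep), len(table.taxon_ids)), dtype=np.int64)
    for i, s in enumerate(keep):
        counts = table.data.loc[s].to_numpy()
        if counts.sum() == depth:
            out[i] = counts
        else:
            out[i] = rng.multivariate_hypergeometric(counts, depth)
    rarefied = CountTable(pd.DataFrame(out, index=keep, columns=table.taxon_ids))
    return rarefied, RarefactionLog(depth=depth, seed=seed, dropped_samples=below)


def to_relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundances (rows sum to 1)."""
    sums = table.row_sums()
    if (sums == 0).any():
        raise ValueError("cannot normalise a sample with zero total reads")
    return table.data.div(sums, axis=0)


def aggregate_taxa(
    data: CountTable | pd.DataFrame,
    taxonomy: TaxonomyTable,
    rank: str = "phylum",
    proteobacteria_to_class: bool = False,
) -> pd.DataFrame:
    """Sum counts/abundances within taxonomic labels at ``rank``.

    Taxa without an assignment at ``rank`` are pooled into 'Unclassified';
    with ``proteobacteria_to_class`` Proteobacteria are resolved to class
    while all other phyla stay at phylum level.  Per-sample totals are
    conserved exactly.
    """
    df = data.data if isinstance(data, CountTable) else data
    labels = taxonomy.label_at(rank, proteobacteria_to_class=proteobacteria_to_class)
    labels = labels.reindex(df.columns).fillna("Unclassified")
    return df.T.groupby(labels).sum().T
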