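"""Reading, writing and preprocessing of ASV count tables.

The central container is :class:`AsvTable`: an integer count matrix
(samples x ASVs) with optional ranked taxonomy and representative
sequences. Preprocessing follows the conventions of compositional
microbiome analysis: low-abundance filtering, closure to relative
abundances, centred log-ratio (CLR) transformation with a pseudo-count
of half the smallest positive relative abundance, alpha-diversity
indices (Shannon, Simpson, Chao1) and seeded rarefaction curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AsvTable",
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
    "filter_asvs",
    "to_relative_abundance",
    "clr_transform",
    "diversity_indices",
    "rarefaction_curve",
]

TAXONOMIC_RANKS = ("division", "class", "order", "family", "genus", "species")


@dataclass
class AsvTable:
    """Integer ASV counts with optional taxonomy and sequences.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, samples as rows, ASVs as
        columns.
    taxonomy
        Optional DataFrame indexed by ASV id with ranked lineage columns
        (division ... species); missing ranks may be NaN or empty.
    sequences
        Optional mapping ASV id -> nucleotide string over {A,C,G,T,N}.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None
    sequences: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        if c.columns.has_duplicates:
            raise ValueError("duplicate ASV ids in count table")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                raise ValueError("counts must be integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if self.taxonomy is not None:
            missing = self.counts.columns.difference(self.taxonomy.index)
            if len(missing):
                raise ValueError(f"taxonomy missing for ASVs: {list(missing)[:5]}")
            self.taxonomy = self.taxonomy.loc[self.counts.columns]
        if self.sequences is not None:
            absent = [a for a in self.counts.columns if a not in self.sequences]
            if absent:
                warnings.warn(
                    f"{len(absent)} ASVs without a representative sequence "
                    f"(e.g. {absent[:3]})",
                    stacklevel=2,
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_asvs(self, asv_ids) -> "AsvTable":
        """Return a new table restricted to ``asv_ids`` (order kept)."""
        asv_ids = [a for a in asv_ids if a in self.counts.columns]
        tax = self.taxonomy.loc[asv_ids] if self.taxonomy is not None else None
        seqs = (
            {a: self.sequences[a] for a in asv_ids if a in self.sequences}
            if self.sequences is not None
            else None
        )
        return AsvTable(self.counts[asv_ids].copy(), tax, seqs)


def read_asv_table(
    counts_path: str | Path,
    taxonomy_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
) -> AsvTable:
    """Load an :class:`AsvTable` from TSV counts (+ taxonomy TSV, FASTA).

    The counts TSV has a header row of ASV ids and sample ids in the
    first column; the taxonomy TSV has the ASV id as first column and
    ranked lineage columns. FASTA record ids must match ASV ids;
    unmatched records are reported with a warning.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count table contains non-numeric entries")

    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        taxonomy.index = taxonomy.index.astype(str)

    sequences = None
    if fasta_path is not None:
        sequences = {}
        extra = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id in counts.columns:
                sequences[rec.id] = str(rec.seq).upper()
            else:
                extra.append(rec.id)
        if extra:
            warnings.warn(f"{len(extra)} FASTA records do not match any ASV id")
    return AsvTable(counts, taxonomy, sequences)


def write_asv_table(table: AsvTable, out_dir: str | Path, prefix: str = "asv") -> dict:
    """Write counts/taxonomy TSV and FASTA; returns the path map.

    Integer counts round-trip bit-exact through :func:`read_asv_table`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"counts": out_dir / f"{prefix}_counts.tsv"}
    table.counts.to_csv(paths["counts"], sep="\t")
    if table.taxonomy is not None:
        paths["taxonomy"] = out_dir / f"{prefix}_taxonomy.tsv"
        table.taxonomy.to_csv(paths["taxonomy"], sep="\t")
    if table.sequences is not None:
        paths["fasta"] = out_dir / f"{prefix}_seqs.fasta"
        records = [
            SeqRecord(Seq(s), id=a, description="")
            for a, s in table.sequences.items()
        ]
        SeqIO.write(records, str(paths["fasta"]), "fasta")
    return {k: str(v) for k, v in paths.items()}


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata TSV (sample id in the first column)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    return meta


def filter_asvs(
    table: AsvTable,
    min_total: int = 50,
    min_samples: int = 3,
    drop_singletons: bool = True,
    per_sample: bool = True,
) -> AsvTable:
    """Remove rare ASVs: singletons, then the 50-in-3 prevalence rule.

    With ``per_sample=True`` (default, the stricter reading) an ASV is
    kept when it has at least ``min_total`` counts in each of at least
    ``min_samples`` samples. With ``per_sample=False`` the alternative
    reading applies: total count >= ``min_total`` and presence in at
    least ``min_samples`` samples. Samples are never dropped. Filtering
    is idempotent.
    """
    counts = table.counts
    keep = pd.Series(True, index=counts.columns)
    if drop_singletons:
        keep &= counts.sum(axis=0) != 1
    if per_sample:
        keep &= (counts >= min_total).sum(axis=0) >= min_samples
    else:
        keep &= (counts.sum(axis=0) >= min_total) & ((counts > 0).sum(axis=0) >= min_samples)
    kept = [a for a in counts.columns if keep[a]]
    if not kept:
        warnings.warn("filter removed every ASV; returning an empty table")
    return table.subset_asvs(kept)


def to_relative_abundance(table: AsvTable | pd.DataFrame) -> pd.DataFrame:
    """Close each sample to relative abundances (rows sum to 1)."""
    counts = table.counts if isinstance(table, AsvTable) else table
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero.index)}")
    return counts.div(totals, axis=0).astype(float)


def clr_transform(relabund: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio transform of a relative-abundance matrix.

    Exact zeros are replaced by half the smallest strictly positive
    value of the whole matrix before taking logs, so the replacement is
    constant across samples. Every output row sums to zero.
    """
    x = relabund.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("relative abundances must be finite")
    if (x < 0).any():
        raise ValueError("relative abundances must be non-negative")
    positive = x[x > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive entries")
    pseudo = positive.min() / 2.0
    x = np.where(x == 0, pseudo, x)
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    out = pd.DataFrame(clr, index=relabund.index, columns=relabund.columns)
    out.attrs["pseudo_count"] = pseudo
    return out


def diversity_indices(table: AsvTable) -> pd.DataFrame:
    """Per-sample Shannon, Simpson and Chao1 estimates.

    Shannon = -sum p ln p; Simpson = 1 - sum p^2 (Gini-Simpson);
    Chao1 = S_obs + F1(F1-1) / (2(F2+1)) with F1/F2 the singleton and
    doubleton counts. Empty samples get NaN for all three.
    """
    counts = table.counts.to_numpy()
    n_samples = counts.shape[0]
    out = np.full((n_samples, 3), np.nan)
    for i in range(n_samples):
        row = counts[i]
        total = row.sum()
        if total == 0:
            continue
        p = row[row > 0] / total
        out[i, 0] = -(p * np.log(p)).sum()
        out[i, 1] = 1.0 - (p**2).sum()
        s_obs = (row > 0).sum()
        f1 = (row == 1).sum()
        f2 = (row == 2).sum()
        out[i, 2] = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return pd.DataFrame(
        out, index=table.counts.index, columns=["shannon", "simpson", "chao1"]
    )


def rarefaction_curve(
    table: AsvTable,
    depths,
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected ASV richness at each rarefaction depth per sample.

    Subsampling is without replacement, averaged over ``n_reps``
    replicates with a fixed seed; the curve is monotone in depth and
    equals observed richness at full depth.
    """
    rng = np.random.default_rng(seed)
    depths = list(depths)
    counts = table.counts.to_numpy()
    result = np.zeros((counts.shape[0], len(depths)))
    for i in range(counts.shape[0]):
        row = counts[i]
        total = int(row.sum())
        pool = np.repeat(np.arange(row.size), row)
        for j, d in enumerate(depths):
            d = int(d)
            if d > total:
                raise ValueError(
                    f"depth {d} exceeds total count {total} of sample "
                    f"{table.counts.index[i]}"
                )
            if d == total:
                result[i, j] = (row > 0).sum()
                continue
            rich = 0.0
            for _ in range(n_reps):
                sub = rng.choice(pool, size=d, replace=False)
                rich += np.unique(sub).size
            result[i, j] = rich / n_reps
    return pd.DataFrame(result, index=table.counts.index, columns=depths)
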