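"""Post-screen gene scoring for FACS-binned pooled CRISPR screens.

Cells carrying a genome-wide sgRNA library are sorted into the top and
bottom thirds of the tandem-reporter Red:Green ratio distribution; sgRNA
abundances in each bin are read out by sequencing. This module turns reads
or count tables into per-gene scores: anchored sgRNA extraction from FASTQ,
median-of-ratios count normalization, a log-fold-change gene enrichment
score between the high and low bins, replicate averaging, and normalization
of every gene's score to that of a reference autophagy-null gene (ATG9A by
default), yielding heat-map-ready gene x reporter matrices.

External beta-score tables in the MAGeCK ``mle`` gene-summary layout can be
fed directly into :func:`average_replicates` / :func:`normalize_by_reference_gene`;
MAGeCK's estimator itself is not reimplemented.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSampleError,
    InvalidInputError,
    InvalidLibraryError,
)

ANCHOR = "CACCG"  # vector sequence immediately 5' of the 20-nt protospacer
GUIDE_LEN = 20
DEFAULT_REFERENCE_GENE = "ATG9A"


# ---------------------------------------------------------------------------
# Containers


@dataclass
class ScreenCounts:
    """sgRNA x sample read-count matrix with guide->gene map and sample metadata.

    ``counts``: DataFrame indexed by sgRNA id, one integer column per sample.
    ``guide_map``: Series sgRNA id -> gene symbol (exactly one gene per guide).
    ``samples``: DataFrame indexed by sample id with columns
    ``reporter``, ``replicate``, ``bin`` (bin in {input, high, low}).
    """

    counts: pd.DataFrame
    guide_map: pd.Series
    samples: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.guide_map.index.has_duplicates:
            dups = self.guide_map.index[self.guide_map.index.duplicated()].unique()
            raise InvalidLibraryError(f"sgRNAs mapped to multiple genes: {list(dups)[:5]}")
        missing = self.counts.index.difference(self.guide_map.index)
        if len(missing):
            raise InvalidLibraryError(f"counted sgRNAs absent from library: {list(missing)[:5]}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise InvalidInputError("read counts must be nonnegative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise InvalidInputError("read counts must be integers")
            self.counts = self.counts.astype(np.int64)
        extra = self.samples.index.symmetric_difference(self.counts.columns)
        if len(extra):
            raise InvalidInputError(f"sample metadata does not match count columns: {list(extra)[:5]}")

    def genes(self) -> np.ndarray:
        return np.unique(self.guide_map.to_numpy())


@dataclass
class GeneScoreTable:
    """Gene x reporter score matrix with provenance.

    ``n_replicates`` records how many replicates entered each cell's mean;
    ``reference`` names the gene used for normalization (None if raw);
    ``unnormalized_columns`` flags columns where the reference was absent
    or zero and normalization was refused.
    """

    scores: pd.DataFrame
    n_replicates: pd.DataFrame | None = None
    reference: str | None = None
    unnormalized_columns: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# FASTQ -> counts


def validate_library(library: pd.DataFrame) -> pd.DataFrame:
    """Check an sgRNA library table (columns: sgrna, gene, sequence).

    Sequences must be unique 20-mers; each sgRNA id maps to one gene.
    """
    required = {"sgrna", "gene", "sequence"}
    if not required.issubset(library.columns):
        raise InvalidLibraryError(f"library must have columns {sorted(required)}")
    seqs = library["sequence"].str.upper()
    if seqs.duplicated().any():
        raise InvalidLibraryError("duplicate guide sequences in library")
    if library["sgrna"].duplicated().any():
        raise InvalidLibraryError("duplicate sgRNA ids in library")
    if not (seqs.str.len() == GUIDE_LEN).all():
        raise InvalidLibraryError(f"guide sequences must be {GUIDE_LEN}-mers")
    out = library.copy()
    out["sequence"] = seqs
    return out


def _iter_fastq_seqs(path):
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip().upper()


def count_sgrnas_from_reads(fastq_path, library: pd.DataFrame):
    """Count sgRNAs by anchored extraction.

    For each read, the first exact occurrence of the 5'-CACCG-3' vector
    anchor is located and the following 20 nt are matched exactly against
    the library. Returns ``(counts, stats)`` where counts is a Series over
    all library sgRNAs (zeros included) and stats tallies ``no_anchor`` and
    ``no_match`` reads.
    """
    library = validate_library(library)
    seq_to_sgrna = dict(zip(library["sequence"], library["sgrna"]))
    tallies = {sg: 0 for sg in library["sgrna"]}
    no_anchor = no_match = total = 0
    for seq in _iter_fastq_seqs(fastq_path):
        total += 1
        pos = seq.find(ANCHOR)
        if pos < 0:
            no_anchor += 1
            continue
        guide = seq[pos + len(ANCHOR): pos + len(ANCHOR) + GUIDE_LEN]
        sg = seq_to_sgrna.get(guide)
        if sg is None:
            no_match += 1
        else:
            tallies[sg] += 1
    counts = pd.Series(tallies, name="count")
    stats = {"total_reads": total, "no_anchor": no_anchor, "no_match": no_match,
             "matched": total - no_anchor - no_match}
    return counts, stats


# ---------------------------------------------------------------------------
# Normalization and scoring


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style).

    Geometric mean per sgRNA over samples is taken across guides detected
    in every sample; each sample's factor is the median ratio to it.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        bad = counts.columns[arr.sum(axis=0) == 0]
        raise DegenerateSampleError(f"all-zero samples: {list(bad)}")
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise DegenerateSampleError("no sgRNA detected in every sample; size factors undefined")
    log_gm = np.log(arr[allpos]).mean(axis=1)
    factors = np.exp(np.median(np.log(arr[allpos]) - log_gm[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame):
    """Scale each sample by its median-of-ratios size factor.

    Returns ``(scaled, factors)``; scaled counts are floats.
    """
    factors = size_factors(counts)
    return counts / factors, factors


def gene_enrichment_score(
    counts: pd.DataFrame,
    guide_map: pd.Series,
    high: str,
    low: str,
    pseudocount: float = 0.5,
    normalize: bool = True,
) -> pd.Series:
    """Per-gene high/low-bin enrichment score.

    Per-sgRNA score = log2((high + c) / (low + c)) on (optionally
    size-factor normalized) counts; per-gene score is the mean over that
    gene's detected sgRNAs. Positive scores mean enrichment in the high
    Red:Green bin — i.e. the knockout suppresses reporter flux for
    reporters whose ratio rises with flux blockage. Genes with zero
    detected sgRNAs in both bins are omitted (missing, not zero).
    """
    sub = counts[[high, low]]
    if normalize:
        sub, _ = normalize_counts(sub)
    detected = sub.sum(axis=1) > 0
    sub = sub[detected]
    per_sgrna = np.log2((sub[high] + pseudocount) / (sub[low] + pseudocount))
    genes = guide_map.reindex(per_sgrna.index)
    return per_sgrna.groupby(genes).mean().rename("score")


def score_screen(sc: ScreenCounts, pseudocount: float = 0.5) -> dict[str, dict[int, pd.Series]]:
    """Score every (reporter, replicate) pair in a ScreenCounts.

    Returns ``{reporter: {replicate: per-gene score Series}}``.
    """
    out: dict[str, dict[int, pd.Series]] = {}
    meta = sc.samples
    for (reporter, replicate), grp in meta.groupby(["reporter", "replicate"]):
        bins = grp["bin"]
        if not {"high", "low"}.issubset(set(bins)):
            continue
        high = grp.index[bins == "high"][0]
        low = grp.index[bins == "low"][0]
        out.setdefault(str(reporter), {})[int(replicate)] = gene_enrichment_score(
            sc.counts, sc.guide_map, high, low, pseudocount=pseudocount
        )
    return out


def average_replicates(scores_by_reporter: dict[str, dict[int, pd.Series]]) -> GeneScoreTable:
    """Arithmetic mean of per-gene scores over available replicates.

    A gene missing from some replicates is averaged over the replicates
    where it is present, with the reduced n recorded.
    """
    cols = {}
    ncols = {}
    for reporter, reps in scores_by_reporter.items():
        df = pd.DataFrame(reps)
        cols[reporter] = df.mean(axis=1)
        ncols[reporter] = df.notna().sum(axis=1)
    scores = pd.DataFrame(cols)
    scores.index.name = "gene"
    n = pd.DataFrame(ncols).reindex(scores.index)
    return GeneScoreTable(scores=scores, n_replicates=n)


def normalize_by_reference_gene(
    table: GeneScoreTable, reference: str = DEFAULT_REFERENCE_GENE
) -> GeneScoreTable:
    """Divide every column by that column's reference-gene score.

    The reference row becomes exactly 1 in every normalized column.
    Columns where the reference is absent or zero are left untouched and
    flagged in ``unnormalized_columns``.
    """
    scores = table.scores.copy()
    flagged = []
    for col in scores.columns:
        ref = scores.at[reference, col] if reference in scores.index else np.nan
        if pd.isna(ref) or ref == 0:
            flagged.append(col)
            continue
        scores[col] = scores[col] / ref
        scores.at[reference, col] = 1.0  # exact, not up to rounding
    return GeneScoreTable(
        scores=scores,
        n_replicates=table.n_replicates,
        reference=reference,
        unnormalized_columns=tuple(flagged),
    )


# ---------------------------------------------------------------------------
# MAGeCK-layout I/O


def read_counts_tsv(path) -> ScreenCounts:
    """Read a MAGeCK ``count``-layout table (sgRNA, gene, then sample columns).

    Sample metadata (reporter/replicate/bin) is parsed from column names of
    the form ``<reporter>_rep<k>_<bin>`` when possible, else left blank.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    sg = cols.get("sgrna")
    gene = cols.get("gene")
    if sg is None or gene is None:
        raise InvalidInputError("count table must have 'sgRNA' and 'gene' columns")
    if df[sg].duplicated().any():
        raise InvalidLibraryError("duplicate sgRNA rows in count table")
    per_gene = df.groupby(sg)[gene].nunique()
    if (per_gene > 1).any():
        raise InvalidLibraryError("an sgRNA is mapped to more than one gene")
    sample_cols = [c for c in df.columns if c not in (sg, gene)]
    counts = df.set_index(sg)[sample_cols]
    guide_map = df.set_index(sg)[gene]
    meta_rows = []
    for c in sample_cols:
        reporter, replicate, bin_ = "", 1, ""
        parts = c.split("_")
        for p in parts:
            if p.startswith("rep") and p[3:].isdigit():
                replicate = int(p[3:])
            elif p in ("input", "high", "low"):
                bin_ = p
        if parts and not parts[0].startswith("rep") and parts[0] not in ("input", "high", "low"):
            reporter = parts[0]
        meta_rows.append(dict(sample=c, reporter=reporter, replicate=replicate, bin=bin_))
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return ScreenCounts(counts=counts, guide_map=guide_map, samples=samples)


def write_counts_tsv(path, sc: ScreenCounts) -> None:
    out = sc.counts.copy()
    out.insert(0, "gene", sc.guide_map.reindex(out.index))
    out.index.name = "sgRNA"
    out.reset_index().to_csv(path, sep="\t", index=False)


def read_mle_gene_summary(path) -> pd.DataFrame:
    """Read a MAGeCK ``mle`` gene-summary table; returns gene x condition betas.

    Keeps the ``<condition>|beta`` columns, stripping the suffix.
    """
    df = pd.read_csv(path, sep="\t")
    gene_col = next((c for c in df.columns if c.lower() == "gene"), None)
    if gene_col is None:
        raise InvalidInputError("gene summary must have a 'Gene' column")
    beta_cols = [c for c in df.columns if c.endswith("|beta")]
    if not beta_cols:
        raise InvalidInputError("gene summary has no '|beta' columns")
    out = df.set_index(gene_col)[beta_cols]
    out.columns = [c[: -len("|beta")] for c in beta_cols]
    out.index.name = "gene"
    return out


def write_gene_score_csv(path, table: GeneScoreTable) -> None:
    """Write the gene x reporter matrix (heat-map table shape)."""
    table.scores.to_csv(path, float_format="%.6g")


def load_gene_score_csv(path) -> GeneScoreTable:
    return GeneScoreTable(scores=pd.read_csv(path, index_col=0))


__all__ = [
    "ANCHOR", "GUIDE_LEN", "DEFAULT_REFERENCE_GENE",
    "ScreenCounts", "GeneScoreTable",
    "validate_library", "count_sgrnas_from_reads",
    "size_factors", "normalize_counts", "gene_enrichment_score", "score_screen",
    "average_replicates", "normalize_by_reference_gene",
    "read_counts_tsv", "write_counts_tsv", "read_mle_gene_summary",
    "write_gene_score_csv", "load_gene_score_csv",
]
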