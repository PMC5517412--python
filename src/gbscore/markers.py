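"""Reference-free marker calling from pooled tag tables.

Tags from all samples are pooled, clustered by single-linkage at a
Hamming threshold (default 3), and each cluster is parsed into SNP loci
as allelic tag pairs differing at exactly one base, accepted on the
balance of their dataset-wide read counts.  Loci are scored as two
presence/absence rows (one per allele); unpaired tags become dominant
presence/absence markers of their restriction fragment ("SilicoDArT").
Markers are then filtered on technical-replicate scoring consistency,
average read depth and call rate.

All marker matrices are binary with a missing code, oriented markers as
rows and samples as columns, on disk as CSV with ``-`` for missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .tags import TagTable

__all__ = [
    "TagCluster", "SNPLocus", "MarkerMatrix",
    "build_count_matrix", "cluster_tags", "parse_snp_loci",
    "call_genotypes", "call_silicodart", "call_markers", "filter_markers",
]

MISSING = "-"


@dataclass
class TagCluster:
    """Dataset-wide tag cluster: member sequences + per-sample counts."""

    sequences: list[str]
    counts: np.ndarray  # (n_members, n_samples)
    samples: list[str]


@dataclass
class SNPLocus:
    """An allelic tag pair differing at exactly one position."""

    ref_tag: str
    alt_tag: str
    snp_offset: int  # 0-based position within the tag
    ref_depths: np.ndarray  # per-sample read counts
    alt_depths: np.ndarray
    balance: float  # min/max of dataset-wide allele counts, in (0, 1]

    def __post_init__(self) -> None:
        d = sum(a != b for a, b in zip(self.ref_tag, self.alt_tag))
        if d != 1:
            raise ValueError("allelic tags must differ at exactly one position")


@dataclass
class MarkerMatrix:
    """Binary presence/absence scores, markers as rows, samples as columns.

    ``scores`` holds 0.0 / 1.0 / NaN (missing); ``meta`` is indexed by
    marker_id with columns type, avg_depth, consistency, call_rate and,
    for SNP rows, snp_offset / ref_tag / alt_tag.
    """

    scores: pd.DataFrame
    meta: pd.DataFrame

    @property
    def n_markers(self) -> int:
        return self.scores.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)

    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        out = self.scores.copy()
        # write integers where called, the missing code elsewhere
        out = out.map(lambda v: MISSING if pd.isna(v) else str(int(v)))
        out.to_csv(path, index_label="marker_id")
        if meta_path is not None:
            self.meta.to_csv(meta_path, index_label="marker_id")

    @classmethod
    def from_csv(cls, path: str | Path,
                 meta_path: str | Path | None = None) -> "MarkerMatrix":
        scores = pd.read_csv(path, index_col="marker_id",
                             na_values=MISSING, keep_default_na=False)
        scores = scores.astype(float)
        if meta_path is not None:
            meta = pd.read_csv(meta_path, index_col="marker_id",
                               keep_default_na=True)
        else:
            meta = pd.DataFrame(index=scores.index)
        return cls(scores=scores, meta=meta)

    @staticmethod
    def concat(matrices: list["MarkerMatrix"]) -> "MarkerMatrix":
        return MarkerMatrix(
            scores=pd.concat([m.scores for m in matrices]),
            meta=pd.concat([m.meta for m in matrices]),
        )


# ---------------------------------------------------------------------------
# pooling and clustering
# ---------------------------------------------------------------------------

def build_count_matrix(table: TagTable) -> tuple[list[str], np.ndarray, list[str]]:
    """Pool tags across samples into (sequences, counts, samples).

    ``counts`` has one row per unique dataset-wide sequence and one
    column per sample.
    """
    samples = sorted(table.tables)
    seqs = sorted({s for t in table.tables.values() for s in t})
    index = {s: i for i, s in enumerate(seqs)}
    counts = np.zeros((len(seqs), len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        for seq, c in table.tables[sid].items():
            counts[index[seq], j] = c
    return seqs, counts, samples


def _encode(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1)


def cluster_tags(sequences: list[str], threshold: int = 3,
                 block: int = 256) -> list[list[int]]:
    """Single-linkage clusters at Hamming distance <= ``threshold``.

    Clusters are the connected components (transitive closure) of the
    graph whose edges join sequence pairs within the threshold.  Returns
    lists of indices into ``sequences``, each sorted, ordered by their
    smallest member.
    """
    if not sequences:
        return []
    if len({len(s) for s in sequences}) != 1:
        raise ValueError("tags must have equal length to be clustered")
    n = len(sequences)
    enc = _encode(sequences)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for start in range(0, n, block):
        stop = min(start + block, n)
        d = (enc[start:stop, None, :] != enc[None, :, :]).sum(axis=2)
        r, c = np.nonzero(d <= threshold)
        rows.append(r + start)
        cols.append(c)
    adj = coo_matrix(
        (np.ones(sum(len(r) for r in rows), dtype=np.int8),
         (np.concatenate(rows), np.concatenate(cols))), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    clusters: list[list[int]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        clusters[lab].append(i)
    clusters.sort(key=lambda c: c[0])
    return clusters


# ---------------------------------------------------------------------------
# cluster parsing and scoring
# ---------------------------------------------------------------------------

def parse_snp_loci(
    cluster: TagCluster,
    min_balance: float = 0.02,
    min_samples_per_allele: int = 2,
) -> tuple[list[SNPLocus], list[int]]:
    """Parse a tag cluster into SNP loci via allelic read-count balance.

    Candidate pairs are cluster members at Hamming distance exactly 1.
    A pair is accepted iff the dataset-wide count balance
    ``min(c1, c2) / max(c1, c2)`` is at least ``min_balance`` and each
    allele is observed (count > 0) in at least
    ``min_samples_per_allele`` samples.  Tags are committed to at most
    one locus, greedily by descending combined count (ties by sequence).
    The reference allele is the higher-count tag of the pair.

    Returns ``(loci, unpaired_member_indices)``.
    """
    seqs = cluster.sequences
    totals = cluster.counts.sum(axis=1)
    enc = _encode(seqs) if seqs else np.empty((0, 0))
    pairs = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if (enc[i] != enc[j]).sum() == 1:
                pairs.append((i, j))
    pairs.sort(key=lambda p: (-(totals[p[0]] + totals[p[1]]),
                              min(seqs[p[0]], seqs[p[1]]),
                              max(seqs[p[0]], seqs[p[1]])))
    assigned: set[int] = set()
    loci: list[SNPLocus] = []
    for i, j in pairs:
        if i in assigned or j in assigned:
            continue
        c1, c2 = totals[i], totals[j]
        balance = min(c1, c2) / max(c1, c2)
        if balance < min_balance:
            continue
        if ((cluster.counts[i] > 0).sum() < min_samples_per_allele
                or (cluster.counts[j] > 0).sum() < min_samples_per_allele):
            continue
        if (c1, seqs[j]) < (c2, seqs[i]):  # ref = higher count, tie by sequence
            i, j = j, i
        offset = int(np.nonzero(enc[i] != enc[j])[0][0])
        loci.append(SNPLocus(
            ref_tag=seqs[i], alt_tag=seqs[j], snp_offset=offset,
            ref_depths=cluster.counts[i].copy(),
            alt_depths=cluster.counts[j].copy(),
            balance=float(balance),
        ))
        assigned.update((i, j))
    unpaired = [i for i in range(len(seqs)) if i not in assigned]
    return loci, unpaired


def call_genotypes(locus: SNPLocus, min_locus_depth: int = 5
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Two presence/absence rows (ref, alt) for one SNP locus.

    Samples whose total locus depth is below ``min_locus_depth`` are
    missing (NaN) on both rows; otherwise each allele row scores 1 iff
    that allele has at least one read.
    """
    total = locus.ref_depths + locus.alt_depths
    covered = total >= min_locus_depth
    ref_row = np.where(covered, (locus.ref_depths >= 1).astype(float), np.nan)
    alt_row = np.where(covered, (locus.alt_depths >= 1).astype(float), np.nan)
    return ref_row, alt_row


def call_silicodart(
    tag_depths: np.ndarray,
    sample_totals: np.ndarray,
    min_depth: int = 5,
    coverage_floor: int = 100,
) -> np.ndarray | None:
    """Dominant presence/absence row for one restriction-fragment tag.

    Scores 1 where the tag's depth reaches ``min_depth``, 0 where the
    sample is adequately covered overall (total reads >=
    ``coverage_floor``) but the tag is absent, missing otherwise.
    Returns None for rows that are not polymorphic (need at least one
    present and one absent call).
    """
    present = tag_depths >= min_depth
    covered = sample_totals >= coverage_floor
    row = np.where(covered | present, present.astype(float), np.nan)
    called = row[~np.isnan(row)]
    if called.size == 0 or called.min() == called.max():
        return None
    return row


def call_markers(
    table: TagTable,
    threshold: int = 3,
    min_balance: float = 0.02,
    min_samples_per_allele: int = 2,
    min_locus_depth: int = 5,
    min_silico_depth: int = 5,
    coverage_floor: int = 100,
    min_dataset_count: int = 2,
) -> tuple[MarkerMatrix, MarkerMatrix]:
    """Full marker discovery: cluster pooled tags, parse SNP loci, score.

    Tags observed fewer than ``min_dataset_count`` times across the whole
    dataset are ignored: such sequences can contribute to no marker (an
    allele must appear in >= 2 samples, a fragment needs depth >=
    ``min_silico_depth``).  Returns the unfiltered (SNP, SilicoDArT)
    matrices; apply :func:`filter_markers` afterwards.
    """
    seqs, counts, samples = build_count_matrix(table)
    keep = counts.sum(axis=1) >= min_dataset_count
    seqs = [s for s, k in zip(seqs, keep) if k]
    counts = counts[keep]
    sample_totals = np.array([table.total_count(s) for s in samples])

    clusters = cluster_tags(seqs, threshold=threshold)
    snp_rows: dict[str, np.ndarray] = {}
    snp_meta: list[dict] = []
    sil_rows: dict[str, np.ndarray] = {}
    sil_meta: list[dict] = []
    n_locus = 0
    n_sil = 0
    for members in clusters:
        tc = TagCluster(
            sequences=[seqs[i] for i in members],
            counts=counts[members], samples=samples,
        )
        loci, unpaired = parse_snp_loci(
            tc, min_balance=min_balance,
            min_samples_per_allele=min_samples_per_allele)
        for locus in loci:
            ref_row, alt_row = call_genotypes(locus, min_locus_depth)
            total = locus.ref_depths + locus.alt_depths
            called = ~np.isnan(ref_row)
            avg_depth = float(total[called].mean()) if called.any() else 0.0
            base = f"snp{n_locus:05d}"
            n_locus += 1
            for suffix, row, tag in (("ref", ref_row, locus.ref_tag),
                                     ("alt", alt_row, locus.alt_tag)):
                mid = f"{base}_{suffix}"
                snp_rows[mid] = row
                snp_meta.append({
                    "marker_id": mid, "type": "SNP", "avg_depth": avg_depth,
                    "snp_offset": locus.snp_offset, "balance": locus.balance,
                    "ref_tag": locus.ref_tag, "alt_tag": locus.alt_tag,
                })
        for i in unpaired:
            row = call_silicodart(tc.counts[i], sample_totals,
                                  min_depth=min_silico_depth,
                                  coverage_floor=coverage_floor)
            if row is None:
                continue
            present = tc.counts[i] > 0
            avg_depth = float(tc.counts[i][present].mean()) if present.any() else 0.0
            mid = f"sil{n_sil:05d}"
            n_sil += 1
            sil_rows[mid] = row
            sil_meta.append({
                "marker_id": mid, "type": "SilicoDArT", "avg_depth": avg_depth,
                "snp_offset": np.nan, "balance": np.nan,
                "ref_tag": tc.sequences[i], "alt_tag": "",
            })

    def _matrix(rows: dict[str, np.ndarray], meta: list[dict]) -> MarkerMatrix:
        scores = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
        mdf = (pd.DataFrame(meta).set_index("marker_id")
               if meta else pd.DataFrame(index=scores.index))
        call_rate = scores.notna().mean(axis=1) if len(scores) else pd.Series(dtype=float)
        mdf["call_rate"] = call_rate
        return MarkerMatrix(scores=scores, meta=mdf)

    return _matrix(snp_rows, snp_meta), _matrix(sil_rows, sil_meta)


def filter_markers(
    matrix: MarkerMatrix,
    replicate_pairs: list[tuple[str, str]] | None,
    min_consistency: float = 0.95,
    min_avg_depth: float = 10.0,
    min_call_rate: float = 0.8,
) -> tuple[MarkerMatrix, dict[str, int]]:
    """Quality-filter markers; returns (filtered matrix, attrition counts).

    Replicate scoring consistency — the fraction of technical-replicate
    pairs, among those where both members are called, on which the two
    calls agree — is the primary criterion; markers also need a minimum
    average read depth and call rate.  Attrition counts one reason per
    dropped marker, applied in the order consistency, depth, call rate.
    """
    scores = matrix.scores
    meta = matrix.meta.copy()
    n = len(scores)
    if replicate_pairs:
        pairs = [(a, b) for a, b in replicate_pairs
                 if a in scores.columns and b in scores.columns]
        if pairs:
            agree = np.zeros(n)
            seen = np.zeros(n)
            for a, b in pairs:
                va, vb = scores[a].to_numpy(), scores[b].to_numpy()
                both = ~np.isnan(va) & ~np.isnan(vb)
                seen += both
                agree += both & (va == vb)
            with np.errstate(invalid="ignore"):
                consistency = np.where(seen > 0, agree / np.maximum(seen, 1), np.nan)
        else:
            consistency = np.full(n, np.nan)
    else:
        warnings.warn("no technical-replicate pairs: consistency filter skipped")
        consistency = np.full(n, np.nan)
    meta["consistency"] = consistency

    cons_fail = ~np.isnan(consistency) & (consistency < min_consistency)
    depth = meta["avg_depth"].to_numpy(dtype=float) if "avg_depth" in meta else np.full(n, np.inf)
    depth_fail = ~cons_fail & (depth < min_avg_depth)
    rate = meta["call_rate"].to_numpy(dtype=float) if "call_rate" in meta else np.ones(n)
    rate_fail = ~cons_fail & ~depth_fail & (rate < min_call_rate)
    keep = ~(cons_fail | depth_fail | rate_fail)
    attrition = {
        "input": n,
        "consistency": int(cons_fail.sum()),
        "depth": int(depth_fail.sum()),
        "call_rate": int(rate_fail.sum()),
        "kept": int(keep.sum()),
    }
    return MarkerMatrix(scores=scores.loc[keep], meta=meta.loc[keep]), attrition
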