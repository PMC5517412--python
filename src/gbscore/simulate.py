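"""Synthetic germplasm and in-silico reduced-representation sequencing.

This module generates everything the downstream marker-calling and
diversity stages need, with known ground truth:

* latent population structure (Balding–Nichols-style divergence around
  shared ancestral allele frequencies),
* accessions organised into clonal redundancy groups (clone mates differ
  only by rare somatic mutations) plus exact technical-replicate copies,
* an in-silico PstI–NspI double-digest fragment library (only "mixed"
  fragments with one end of each enzyme, within a size window, and free
  of AlwI sites, are retained — emulating the selective-amplification
  step of the assay), with a single high-copy chloroplast-like decoy
  fragment,
* single-end FASTQ reads of fixed cycle number carrying inline
  staggered (variable-length) barcodes.

Two kinds of polymorphism are planted: biallelic SNPs inside fragments
(one per fragment) and presence/absence variation (whole fragments
deleted in some accessions).  Both are governed by the same population
model, so structure is recoverable from either marker class.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PopulationModel",
    "AccessionTruth",
    "Fragment",
    "FragmentLibrary",
    "BarcodeManifest",
    "simulate_populations",
    "simulate_accessions",
    "random_genome",
    "digest_genome",
    "make_manifest",
    "generate_reads",
    "expected_tag_pair",
    "EmptyLibraryError",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTRY", "TGCAYR")

#: adapter-like filler appended when insert + barcode is shorter than the
#: read length (short fragments are sequenced into the adapter)
ADAPTER_FILL = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAGACCGATCTCGTATGCCGTCTTCTGCTTGAAAAAAAAAAAA"

PSTI = "CTGCAG"
NSPI = "RCATGY"
ALWI = "GGATC"

QUAL_HIGH = 35  # Phred score written for correctly simulated bases
QUAL_LOW = 12   # Phred score written for substituted (error) bases


class EmptyLibraryError(ValueError):
    """Raised when a digest yields no usable mixed fragments."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_to_regex(motif: str) -> str:
    table = {"R": "[AG]", "Y": "[CT]", "N": "[ACGT]"}
    return "".join(table.get(b, b) for b in motif)


# ---------------------------------------------------------------------------
# population model and accessions
# ---------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Per-population allele frequencies for ``n_loci`` biallelic loci.

    ``allele_freqs`` has shape (n_pops, n_loci); ``ancestral_freqs`` the
    shared frequencies the populations diverged from.  ``fst`` controls
    the Balding–Nichols dispersion of population frequencies around the
    ancestral ones.
    """

    n_pops: int
    n_loci: int
    allele_freqs: np.ndarray
    fst: float
    ancestral_freqs: np.ndarray

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_loci < 1:
            raise ValueError("n_pops and n_loci must be >= 1")
        if np.any(self.allele_freqs < 0) or np.any(self.allele_freqs > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass
class AccessionTruth:
    """Ground truth for one simulated accession (or technical replicate)."""

    accession_id: str
    pop_label: int
    admixture: np.ndarray
    haplotype: np.ndarray
    clone_group: int | None = None
    is_replicate_of: str | None = None

    def __post_init__(self) -> None:
        if abs(float(self.admixture.sum()) - 1.0) > 1e-9:
            raise ValueError("admixture proportions must sum to 1")


@dataclass
class Fragment:
    fragment_id: str
    sequence: str
    copy_weight: float = 1.0


@dataclass
class FragmentLibrary:
    """Retained mixed (PstI–NspI) fragments plus planted polymorphism.

    ``variant_map`` maps SNP locus index -> (fragment_id, offset,
    ref_base, alt_base); ``pav_map`` maps presence/absence locus index ->
    fragment_id (haplotype 0 at that locus means the fragment is deleted
    in that accession).
    """

    fragments: list[Fragment]
    variant_map: dict[int, tuple[str, int, str, str]]
    insert_range: tuple[int, int]
    pav_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {f.fragment_id: f for f in self.fragments}

    def __len__(self) -> int:
        return len(self.fragments)

    def get(self, fragment_id: str) -> Fragment:
        return self._by_id[fragment_id]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in self.fragments:
                fh.write(f">{f.fragment_id} copy_weight={f.copy_weight:g}\n")
                fh.write(f.sequence + "\n")


@dataclass
class BarcodeManifest:
    """sample_id -> inline barcode (length 5-8 nt), plus replicate pairing.

    Barcodes are unique and mutually prefix-free so that exact-prefix
    demultiplexing is unambiguous.
    """

    barcodes: dict[str, str]
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = list(self.barcodes.values())
        if len(set(codes)) != len(codes):
            raise ValueError("barcodes must be unique")
        for a in codes:
            for b in codes:
                if a != b and b.startswith(a):
                    raise ValueError(f"barcode {a!r} is a prefix of {b!r}")

    @property
    def max_barcode_length(self) -> int:
        return max(len(b) for b in self.barcodes.values())

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_id", "barcode"])
            for sid, bc in self.barcodes.items():
                w.writerow([sid, bc])

    @classmethod
    def from_csv(cls, path: str | Path) -> "BarcodeManifest":
        barcodes: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                barcodes[row["sample_id"]] = row["barcode"]
        return cls(barcodes=barcodes)


def simulate_populations(
    n_pops: int,
    n_loci: int,
    fst: float,
    seed: int,
    ancestral_range: tuple[float, float] = (0.1, 0.9),
) -> PopulationModel:
    """Draw per-population allele frequencies under a Balding–Nichols model.

    Ancestral frequencies are uniform on ``ancestral_range``; each
    population's frequency at locus l is Beta(p(1-F)/F, (1-p)(1-F)/F),
    so between-population variance grows with ``fst``.  With a single
    population the ancestral frequencies are returned unchanged.
    """
    if n_pops < 1 or n_loci < 1:
        raise ValueError("n_pops and n_loci must be positive")
    if not (0.0 < fst < 1.0):
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = ancestral_range
    anc = rng.uniform(lo, hi, size=n_loci)
    if n_pops == 1:
        freqs = anc[None, :].copy()
    else:
        a = anc * (1.0 - fst) / fst
        b = (1.0 - anc) * (1.0 - fst) / fst
        freqs = rng.beta(a[None, :], b[None, :], size=(n_pops, n_loci))
    return PopulationModel(
        n_pops=n_pops, n_loci=n_loci, allele_freqs=freqs, fst=fst,
        ancestral_freqs=anc,
    )


def simulate_accessions(
    model: PopulationModel,
    sizes: int | list[int],
    clone_spec: list[int] | None = None,
    somatic_rate: float = 0.0,
    n_replicate_pairs: int = 0,
    seed: int = 0,
) -> list[AccessionTruth]:
    """Draw accession haplotypes, organise clonal groups and replicates.

    ``sizes`` is either the total accession count (split near-evenly over
    populations) or a per-population list.  Each clone group listed in
    ``clone_spec`` (sizes >= 2) claims consecutive accessions inside one
    population: the founder haplotype is copied and each locus flipped
    independently with probability ``somatic_rate``.  Technical
    replicates are appended as exact haplotype copies of distinct
    accessions, flagged ``is_replicate_of`` (ids suffixed ``_rep``).
    """
    clone_spec = list(clone_spec or [])
    if not (0.0 <= somatic_rate <= 0.01):
        raise ValueError("somatic_rate must be in [0, 0.01]")
    if any(g < 2 for g in clone_spec):
        raise ValueError("clone groups must have size >= 2")
    if isinstance(sizes, int):
        base = sizes // model.n_pops
        per_pop = [base] * model.n_pops
        for i in range(sizes - base * model.n_pops):
            per_pop[i] += 1
    else:
        per_pop = list(sizes)
    if len(per_pop) != model.n_pops:
        raise ValueError("sizes must match n_pops")
    n_total = sum(per_pop)
    if sum(clone_spec) > n_total:
        raise ValueError("requested clone members exceed accession count")

    rng = np.random.default_rng(seed)
    # assign clone groups to populations (largest group to roomiest pop);
    # a group larger than the even per-population share is allowed and the
    # independent-accession counts are rebalanced so the total stays exact
    capacity = list(per_pop)
    group_pop: list[int] = []
    for g in sorted(clone_spec, reverse=True):
        pop = int(np.argmax(capacity))
        capacity[pop] -= g
        group_pop.append(pop)
    while min(capacity) < 0:
        deficit_pop = int(np.argmin(capacity))
        donor = int(np.argmax(capacity))
        if capacity[donor] <= 0:
            raise ValueError("requested clone members exceed accession count")
        move = min(capacity[donor], -capacity[deficit_pop])
        capacity[donor] -= move
        capacity[deficit_pop] += move
    order = np.argsort(np.argsort(-np.array(clone_spec, dtype=int), kind="stable"))
    group_pop = [group_pop[i] for i in order] if clone_spec else []

    accessions: list[AccessionTruth] = []
    width = max(3, len(str(n_total)))
    counter = 0

    def _new_id() -> str:
        nonlocal counter
        aid = f"A{counter:0{width}d}"
        counter += 1
        return aid

    def _draw(pop: int) -> np.ndarray:
        return (rng.random(model.n_loci) < model.allele_freqs[pop]).astype(np.uint8)

    def _admix(pop: int) -> np.ndarray:
        q = np.zeros(model.n_pops)
        q[pop] = 1.0
        return q

    remaining = capacity  # independent accessions per pop after groups
    # clone groups first (deterministic placement), then independent accessions
    for gidx, (gsize, pop) in enumerate(zip(clone_spec, group_pop)):
        founder = _draw(pop)
        for _ in range(gsize):
            hap = founder.copy()
            if somatic_rate > 0:
                flips = rng.random(model.n_loci) < somatic_rate
                hap[flips] ^= 1
            accessions.append(AccessionTruth(
                accession_id=_new_id(), pop_label=pop, admixture=_admix(pop),
                haplotype=hap, clone_group=gidx,
            ))
    for pop in range(model.n_pops):
        for _ in range(remaining[pop]):
            accessions.append(AccessionTruth(
                accession_id=_new_id(), pop_label=pop, admixture=_admix(pop),
                haplotype=_draw(pop),
            ))

    if n_replicate_pairs > len(accessions):
        raise ValueError("more replicate pairs than accessions")
    rep_sources = rng.choice(len(accessions), size=n_replicate_pairs, replace=False)
    for i in sorted(int(i) for i in rep_sources):
        src = accessions[i]
        accessions.append(AccessionTruth(
            accession_id=src.accession_id + "_rep",
            pop_label=src.pop_label,
            admixture=src.admixture.copy(),
            haplotype=src.haplotype.copy(),
            clone_group=src.clone_group,
            is_replicate_of=src.accession_id,
        ))
    return accessions


# ---------------------------------------------------------------------------
# in-silico digestion
# ---------------------------------------------------------------------------

def random_genome(length: int, seed: int) -> str:
    """Uniform random ACGT string (stand-in for a real genome at desk scale)."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _cut_positions(genome: str, motif: str) -> list[int]:
    """Midpoint cut coordinates for all occurrences of an IUPAC motif."""
    half = len(motif) // 2
    return [m.start() + half for m in re.finditer(_iupac_to_regex(motif), genome)]


def digest_genome(
    genome: str | None = None,
    genome_length: int = 2_000_000,
    n_variants: int = 0,
    n_pav: int = 0,
    motif_pstI: str = PSTI,
    motif_nspI: str = NSPI,
    motif_alwI: str = ALWI,
    insert_range: tuple[int, int] = (30, 60),
    chloroplast_copy_weight: float = 40.0,
    max_fragments: int | None = None,
    seed: int = 0,
) -> FragmentLibrary:
    """In-silico PstI–NspI double digest with AlwI counter-selection.

    Retains only "mixed" fragments — spans between adjacent cut sites of
    the two different enzymes — whose length lies inside ``insert_range``
    and which carry no AlwI site on either strand.  Fragments are stored
    PstI-end-first (reverse-complemented when needed; both recognition
    motifs are palindromic so the half-site invariant is orientation
    free).  One fragment is designated a high-copy chloroplast-like
    decoy.  SNPs (``n_variants``, one per fragment) and whole-fragment
    presence/absence loci (``n_pav``) are planted in disjoint fragment
    sets, never inside the 3-bp half-sites.
    """
    if genome is None:
        genome = random_genome(genome_length, seed)
    rng = np.random.default_rng(seed + 1)

    cuts = sorted(
        [(c, "P") for c in _cut_positions(genome, motif_pstI)]
        + [(c, "N") for c in _cut_positions(genome, motif_nspI)]
    )
    lo, hi = insert_range
    fragments: list[Fragment] = []
    for (c1, e1), (c2, e2) in zip(cuts, cuts[1:]):
        if e1 == e2:
            continue
        seq = genome[c1:c2]
        if not (lo <= len(seq) <= hi):
            continue
        if motif_alwI in seq or _revcomp(motif_alwI) in seq:
            continue
        if e1 == "N":  # orient PstI end first
            seq = _revcomp(seq)
        fragments.append(Fragment(fragment_id=f"F{len(fragments):05d}", sequence=seq))
    if not fragments:
        raise EmptyLibraryError(
            "digest produced no mixed fragments in the size window; "
            "use a longer genome"
        )
    if max_fragments is not None and len(fragments) > max_fragments:
        keep = sorted(rng.choice(len(fragments), size=max_fragments, replace=False))
        fragments = [fragments[int(i)] for i in keep]
        for i, f in enumerate(fragments):
            f.fragment_id = f"F{i:05d}"

    if n_variants + n_pav + 1 > len(fragments):
        raise EmptyLibraryError(
            f"library has {len(fragments)} fragments but "
            f"{n_variants + n_pav} polymorphic loci plus a decoy were requested"
        )

    # decoy gets the high copy weight; polymorphism goes elsewhere
    decoy_idx = int(rng.integers(len(fragments)))
    fragments[decoy_idx].copy_weight = float(chloroplast_copy_weight)
    eligible = [i for i in range(len(fragments)) if i != decoy_idx]
    chosen = rng.choice(len(eligible), size=n_variants + n_pav, replace=False)
    chosen = [eligible[int(i)] for i in chosen]

    variant_map: dict[int, tuple[str, int, str, str]] = {}
    for locus, fi in enumerate(chosen[:n_variants]):
        frag = fragments[fi]
        # keep SNPs clear of the 3-bp half-sites at both ends
        offset = int(rng.integers(3, len(frag.sequence) - 3))
        ref = frag.sequence[offset]
        alt = rng.choice([b for b in BASES if b != ref])
        variant_map[locus] = (frag.fragment_id, offset, ref, str(alt))
    pav_map = {
        n_variants + j: fragments[fi].fragment_id
        for j, fi in enumerate(chosen[n_variants:])
    }
    return FragmentLibrary(
        fragments=fragments, variant_map=variant_map,
        insert_range=insert_range, pav_map=pav_map,
    )


# ---------------------------------------------------------------------------
# barcodes and reads
# ---------------------------------------------------------------------------

def make_manifest(
    accessions: list[AccessionTruth],
    seed: int = 0,
    lengths: tuple[int, ...] = (5, 6, 7, 8),
) -> BarcodeManifest:
    """Assign unique, prefix-free staggered barcodes to every accession."""
    rng = np.random.default_rng(seed)
    barcodes: dict[str, str] = {}
    taken: list[str] = []
    for i, acc in enumerate(accessions):
        length = lengths[i % len(lengths)]
        for _ in range(10_000):
            bc = "".join(rng.choice(list(BASES), size=length))
            if all(not bc.startswith(t) and not t.startswith(bc) for t in taken):
                taken.append(bc)
                barcodes[acc.accession_id] = bc
                break
        else:  # pragma: no cover - barcode space exhausted
            raise RuntimeError("could not find a prefix-free barcode")
    pairs = [
        (a.is_replicate_of, a.accession_id)
        for a in accessions if a.is_replicate_of is not None
    ]
    return BarcodeManifest(barcodes=barcodes, replicate_pairs=pairs)


def _allele_sequence(frag: Fragment, variant: tuple[str, int, str, str] | None,
                     allele: int) -> str:
    seq = frag.sequence
    if variant is not None and allele == 1:
        _, offset, _, alt = variant
        seq = seq[:offset] + alt + seq[offset + 1:]
    return seq


def expected_tag_pair(
    library: FragmentLibrary, locus: int, tag_length: int
) -> tuple[str, str]:
    """The (ref, alt) tag sequences a perfect pipeline would recover for
    a planted SNP, i.e. the allele sequences padded with the adapter fill
    and trimmed to the common tag length."""
    frag_id, offset, ref, alt = library.variant_map[locus]
    frag = library.get(frag_id)
    ref_seq = (frag.sequence + ADAPTER_FILL)[:tag_length]
    alt_full = frag.sequence[:offset] + alt + frag.sequence[offset + 1:]
    alt_seq = (alt_full + ADAPTER_FILL)[:tag_length]
    return ref_seq, alt_seq


def generate_reads(
    library: FragmentLibrary,
    accessions: list[AccessionTruth],
    manifest: BarcodeManifest,
    out_dir: str | Path,
    mean_depth: float = 20.0,
    error_rate: float = 0.0,
    read_length: int = 77,
    seed: int = 0,
) -> dict[str, Path]:
    """Simulate barcoded single-end reads and write FASTQ plus truth tables.

    Each read is barcode + the accession's allele sequence of one
    fragment, padded with adapter fill to ``read_length`` (inserts are
    shorter than the cycle number).  Per-(sample, fragment) depth is
    Poisson(mean_depth x copy_weight); fragments deleted under a
    presence/absence locus yield no reads.  Substitution errors are
    i.i.d. at ``error_rate`` with low quality scores at error positions.
    Read ids encode sample and fragment of origin.

    Returns a dict of written paths: ``reads`` (FASTQ), ``manifest``,
    ``accessions``, ``genotypes``, ``read_counts``, ``fragments``.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not (0.0 <= error_rate <= 0.05):
        raise ValueError("error_rate must be in [0, 0.05]")
    for sid in manifest.barcodes:
        if not any(a.accession_id == sid for a in accessions):
            raise ValueError(f"manifest sample {sid!r} not among accessions")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    frag_variant = {var[0]: (locus, var)
                    for locus, var in library.variant_map.items()}
    pav_by_frag = {fid: locus for locus, fid in library.pav_map.items()}

    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    fastq_path = out_dir / "reads.fastq"
    counts_rows: list[tuple[str, str, int]] = []
    with open(fastq_path, "w") as fq:
        for acc in accessions:
            if acc.accession_id not in manifest.barcodes:
                continue
            barcode = manifest.barcodes[acc.accession_id]
            for frag in library.fragments:
                pav_locus = pav_by_frag.get(frag.fragment_id)
                if pav_locus is not None and acc.haplotype[pav_locus] == 0:
                    continue  # fragment deleted in this accession
                lv = frag_variant.get(frag.fragment_id)
                allele = int(acc.haplotype[lv[0]]) if lv else 0
                template = (barcode
                            + _allele_sequence(frag, lv[1] if lv else None, allele)
                            + ADAPTER_FILL)[:read_length]
                depth = int(rng.poisson(mean_depth * frag.copy_weight))
                if depth == 0:
                    continue
                counts_rows.append((acc.accession_id, frag.fragment_id, depth))
                tmpl = np.frombuffer(template.encode(), dtype=np.uint8)
                for r in range(depth):
                    seq = tmpl.copy()
                    qual = np.full(read_length, QUAL_HIGH + 33, dtype=np.uint8)
                    if error_rate > 0:
                        err = np.nonzero(rng.random(read_length) < error_rate)[0]
                        if err.size:
                            shift = rng.integers(1, 4, size=err.size)
                            idx = np.searchsorted(base_arr, seq[err])
                            seq[err] = base_arr[(idx + shift) % 4]
                            qual[err] = QUAL_LOW + 33
                    rid = f"{acc.accession_id}|{frag.fragment_id}|{r}"
                    fq.write(f"@{rid}\n{seq.tobytes().decode()}\n+\n"
                             f"{qual.tobytes().decode()}\n")

    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path)
    acc_path = out_dir / "accessions.csv"
    with open(acc_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["accession_id", "pop_label", "clone_group", "is_replicate_of"])
        for a in accessions:
            w.writerow([a.accession_id, a.pop_label,
                        "" if a.clone_group is None else a.clone_group,
                        a.is_replicate_of or ""])
    geno_path = out_dir / "genotypes.csv"
    with open(geno_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["accession_id", "locus", "genotype"])
        for a in accessions:
            for locus, g in enumerate(a.haplotype):
                w.writerow([a.accession_id, locus, int(g)])
    counts_path = out_dir / "read_counts.csv"
    with open(counts_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "fragment_id", "n_reads"])
        w.writerows(counts_rows)
    frag_path = out_dir / "fragments.fasta"
    library.to_fasta(frag_path)
    return {
        "reads": fastq_path, "manifest": manifest_path,
        "accessions": acc_path, "genotypes": geno_path,
        "read_counts": counts_path, "fragments": frag_path,
    }
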