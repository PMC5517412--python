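"""End-to-end orchestration: simulate -> tags -> markers -> diversity ->
structure, with a run report and truth-based evaluation helpers.

The pipeline is fully deterministic under a fixed config: the global
seed is propagated to every stage, and rerunning the same config
reproduces every artifact byte for byte.
"""

from __future__ import annotations

import time
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import diversity as dv
from . import markers as mk
from . import simulate as sim
from . import structure as st
from . import tags as tg

__all__ = [
    "SimulateParams", "TagParams", "MarkerParams", "DiversityParams",
    "StructureParams", "PipelineConfig", "RunReport",
    "redundancy_summary", "concordance", "run_all", "evaluate_truth",
]


@dataclass
class SimulateParams:
    n_pops: int = 3
    n_accessions: int = 60
    fst: float = 0.3
    n_snp: int = 260
    n_pav: int = 20
    clone_sizes: tuple[int, ...] = (2, 3, 5, 8, 10)
    somatic_rate: float = 0.0
    n_replicate_pairs: int = 3
    n_fragments: int = 300
    genome_length: int | None = None  # default: sized from n_fragments
    mean_depth: float = 20.0
    error_rate: float = 0.0
    read_length: int = 77
    chloroplast_copy_weight: float = 40.0


@dataclass
class TagParams:
    min_mean_quality: float = 20.0
    barcode_max_mismatch: int = 0
    groom: bool = True
    max_edit: int = 1
    min_template_count: int = 2


@dataclass
class MarkerParams:
    threshold: int = 3
    min_balance: float = 0.02
    min_samples_per_allele: int = 2
    min_locus_depth: int = 5
    min_silico_depth: int = 5
    coverage_floor: int = 100
    min_dataset_count: int = 2
    min_consistency: float = 0.95
    min_avg_depth: float = 10.0
    min_call_rate: float = 0.8


@dataclass
class DiversityParams:
    epsilon: float | None = None      # None: calibrate from replicates
    epsilon_inflation: float = 2.0
    epsilon_floor: float = 0.02       # somatic-divergence allowance
    n_boot: int = 100
    treatment: str = "symmetric"


@dataclass
class StructureParams:
    enabled: bool = True
    k_min: int = 1
    k_max: int = 3
    n_runs: int = 5
    burnin: int = 10_000
    reps: int = 20_000
    assign_threshold: float = 0.8
    # fit on the core collection when redundancy groups are known:
    # duplicated genotypes violate the model's no-LD assumption and bias
    # the likelihood toward spurious extra clusters; redundant members
    # inherit their representative's memberships afterwards
    dedupe: bool = True


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "gbscore_run"
    run_simulate: bool = True
    run_tags: bool = True
    run_markers: bool = True
    run_diversity: bool = True
    run_structure: bool = True
    markers_csv: str | None = None    # external matrix for partial pipelines
    simulate: SimulateParams = field(default_factory=SimulateParams)
    tags: TagParams = field(default_factory=TagParams)
    markers: MarkerParams = field(default_factory=MarkerParams)
    diversity: DiversityParams = field(default_factory=DiversityParams)
    structure: StructureParams = field(default_factory=StructureParams)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        blocks = {
            "simulate": SimulateParams, "tags": TagParams,
            "markers": MarkerParams, "diversity": DiversityParams,
            "structure": StructureParams,
        }
        kwargs: dict = {k: v for k, v in raw.items() if k not in blocks}
        for name, klass in blocks.items():
            params = raw.get(name, {})
            if "clone_sizes" in params:
                params["clone_sizes"] = tuple(params["clone_sizes"])
            kwargs[name] = klass(**params)
        return cls(**kwargs)


@dataclass
class RunReport:
    """Headline numbers of one pipeline run plus in-memory artifacts."""

    accounting: dict = field(default_factory=dict)
    attrition: dict = field(default_factory=dict)
    n_snp_markers: int = 0
    n_silico_markers: int = 0
    redundancy: dict = field(default_factory=dict)
    selected_k: int | None = None
    concordance: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def to_markdown(self, path: str | Path) -> None:
        lines = ["# Pipeline run report", ""]
        lines.append("## Read accounting")
        for k, v in self.accounting.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
        lines.append("## Markers")
        lines.append(f"- SNP marker rows kept: {self.n_snp_markers}")
        lines.append(f"- SilicoDArT markers kept: {self.n_silico_markers}")
        for mat, att in self.attrition.items():
            lines.append(f"- attrition[{mat}]: {att}")
        lines.append("")
        if self.redundancy:
            lines.append("## Redundancy")
            for k, v in self.redundancy.items():
                lines.append(f"- {k}: {v}")
            lines.append("")
        if self.selected_k is not None:
            lines.append(f"## Structure\n- selected K: {self.selected_k}")
            lines.append("")
        if self.concordance:
            lines.append("## Concordance")
            for k, v in self.concordance.items():
                lines.append(f"- {k}: {v}")
        Path(path).write_text("\n".join(lines) + "\n")


def redundancy_summary(n_total: int, n_redundant: int,
                       n_groups: int | None = None) -> dict:
    """Core-collection accounting from redundancy counts.

    ``n_redundant`` counts the non-representative members of redundancy
    groups, i.e. the accessions a core collection drops; the core keeps
    ``n_total - n_redundant`` accessions and the percent reduction is
    ``100 * n_redundant / n_total`` (printed to two decimals).
    """
    if n_redundant > n_total:
        raise ValueError("n_redundant cannot exceed n_total")
    n_unique = n_total - n_redundant
    pct = 100.0 * n_redundant / n_total
    out = {
        "n_total": n_total,
        "n_unique": n_unique,
        "n_redundant": n_redundant,
        "pct_reduction": round(pct, 2),
        "pct_reduction_str": f"{pct:.2f}",
    }
    if n_groups is not None:
        out["n_groups"] = n_groups
    return out


def concordance(partitions: dict[str, dict[str, object]],
                exclude_labels: tuple[str, ...] = ("admixed",)) -> dict:
    """Pairwise chance-corrected agreement between sample partitions.

    ``partitions`` maps method name -> {sample_id: label}.  Samples
    carrying an excluded label (e.g. below the structure membership
    threshold) are removed from every comparison and counted.  All
    partitions must cover the same sample set.
    """
    names = sorted(partitions)
    keysets = {frozenset(partitions[n]) for n in names}
    if len(keysets) != 1:
        raise ValueError("partitions must cover the same samples")
    excluded = {s for n in names for s, lab in partitions[n].items()
                if lab in exclude_labels}
    samples = sorted(next(iter(keysets)) - excluded)
    out: dict = {"n_excluded": len(excluded), "n_compared": len(samples)}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            la = [partitions[a][s] for s in samples]
            lb = [partitions[b][s] for s in samples]
            out[f"{a}~{b}"] = float(adjusted_rand_score(la, lb))
    return out


def _structure_locus_matrix(snp_matrix: mk.MarkerMatrix) -> pd.DataFrame:
    """One presence row per SNP locus (the ref-allele row): with haploid
    binary genotypes the two allele rows are complementary, and feeding
    both would double-count every locus."""
    ref_rows = [m for m in snp_matrix.scores.index if str(m).endswith("_ref")]
    return snp_matrix.scores.loc[ref_rows]


def run_all(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order and assemble the run report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    art = report.artifacts
    timings = report.timings

    class _stage:
        """Times a stage; failures abort with the stage name and the
        manifest of artifacts produced so far."""

        def __init__(self, name: str) -> None:
            self.name = name

        def __enter__(self):
            self.t0 = time.perf_counter()

        def __exit__(self, exc_type, exc, tb):
            timings[self.name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                raise RuntimeError(
                    f"pipeline stage {self.name!r} failed; artifacts so "
                    f"far: {sorted(art)}") from exc

    # ---------------- simulate ----------------
    with _stage("simulate"):
        if config.run_simulate:
            sp = config.simulate
            n_loci = sp.n_snp + sp.n_pav
            model = sim.simulate_populations(sp.n_pops, n_loci, sp.fst,
                                             seed=config.seed)
            accessions = sim.simulate_accessions(
                model, sp.n_accessions, clone_spec=list(sp.clone_sizes),
                somatic_rate=sp.somatic_rate,
                n_replicate_pairs=sp.n_replicate_pairs, seed=config.seed + 1)
            genome_length = sp.genome_length or sp.n_fragments * 120_000
            library = sim.digest_genome(
                genome_length=genome_length, n_variants=sp.n_snp, n_pav=sp.n_pav,
                chloroplast_copy_weight=sp.chloroplast_copy_weight,
                max_fragments=sp.n_fragments, seed=config.seed + 2)
            manifest = sim.make_manifest(accessions, seed=config.seed + 3)
            paths = sim.generate_reads(
                library, accessions, manifest, out_dir / "simulated",
                mean_depth=sp.mean_depth, error_rate=sp.error_rate,
                read_length=sp.read_length, seed=config.seed + 4)
            art.update(model=model, accessions=accessions, library=library,
                       manifest=manifest, paths=paths)

    # ---------------- tags ----------------
    with _stage("tags"):
        if config.run_tags:
            tp = config.tags
            per_sample, acct = tg.demultiplex(
                art["paths"]["reads"], art["manifest"],
                barcode_max_mismatch=tp.barcode_max_mismatch,
                min_mean_quality=tp.min_mean_quality)
            table_raw = tg.collapse(per_sample, acct)
            table = (tg.groom(table_raw, max_edit=tp.max_edit,
                              min_template_count=tp.min_template_count)
                     if tp.groom else table_raw)
            tg.write_tag_tables(table, out_dir / "tags")
            report.accounting = dict(acct)
            report.accounting["groomed_singletons"] = table.groomed_singletons
            art.update(tag_table_raw=table_raw, tag_table=table)

    # ---------------- markers ----------------
    with _stage("markers"):
        if config.run_markers:
            mp = config.markers
            snp_raw, sil_raw = mk.call_markers(
                art["tag_table"], threshold=mp.threshold,
                min_balance=mp.min_balance,
                min_samples_per_allele=mp.min_samples_per_allele,
                min_locus_depth=mp.min_locus_depth,
                min_silico_depth=mp.min_silico_depth,
                coverage_floor=mp.coverage_floor,
                min_dataset_count=mp.min_dataset_count)
            rep_pairs = art["manifest"].replicate_pairs
            snp, att_snp = mk.filter_markers(
                snp_raw, rep_pairs, min_consistency=mp.min_consistency,
                min_avg_depth=mp.min_avg_depth, min_call_rate=mp.min_call_rate)
            sil, att_sil = mk.filter_markers(
                sil_raw, rep_pairs, min_consistency=mp.min_consistency,
                min_avg_depth=mp.min_avg_depth, min_call_rate=mp.min_call_rate)
            snp.to_csv(out_dir / "snp_markers.csv", out_dir / "snp_markers_meta.csv")
            sil.to_csv(out_dir / "silicodart_markers.csv",
                       out_dir / "silicodart_markers_meta.csv")
            report.attrition = {"snp": att_snp, "silicodart": att_sil}
            report.n_snp_markers = snp.n_markers
            report.n_silico_markers = sil.n_markers
            art.update(snp_matrix_raw=snp_raw, silico_matrix_raw=sil_raw,
                       snp_matrix=snp, silico_matrix=sil)
        elif config.markers_csv is not None:
            matrix = mk.MarkerMatrix.from_csv(config.markers_csv)
            art.update(snp_matrix=matrix,
                       silico_matrix=mk.MarkerMatrix(
                           scores=matrix.scores.iloc[0:0],
                           meta=matrix.meta.iloc[0:0]))

    # ---------------- diversity ----------------
    with _stage("diversity"):
        if config.run_diversity:
            dp = config.diversity
            combined = mk.MarkerMatrix.concat(
                [art["snp_matrix"], art["silico_matrix"]])
            D = dv.gower_distance(combined, treatment=dp.treatment)
            rep_pairs = (art["manifest"].replicate_pairs
                         if "manifest" in art else [])
            if dp.epsilon is not None:
                epsilon = dp.epsilon
            elif rep_pairs:
                epsilon = dv.calibrate_epsilon(D, rep_pairs,
                                               inflation=dp.epsilon_inflation,
                                               floor=dp.epsilon_floor)
            else:
                epsilon = max(0.01, dp.epsilon_floor)
            partition = dv.find_redundant(D, epsilon)
            core = dv.core_collection(partition)
            tree = dv.bootstrap_support(combined, n_boot=dp.n_boot,
                                        seed=config.seed + 5,
                                        treatment=dp.treatment)
            ordination = dv.pcoa(D)
            D.to_csv(out_dir / "gower_distances.csv")
            D.to_phylip(out_dir / "gower_distances.phy")
            partition.to_csv(out_dir / "redundancy_groups.csv")
            (out_dir / "core_collection.txt").write_text("\n".join(core) + "\n")
            tree.to_newick(out_dir / "dendrogram.nwk")
            ordination.to_csv(out_dir / "pcoa_coordinates.csv",
                              out_dir / "pcoa_eigenvalues.csv")
            n_total = D.n
            report.redundancy = redundancy_summary(
                n_total, partition.n_redundant, n_groups=len(partition.groups))
            report.redundancy["epsilon"] = epsilon
            report.redundancy["core_size"] = len(core)
            art.update(distance=D, partition=partition, core=core, tree=tree,
                       pcoa=ordination, combined_matrix=combined)

    # ---------------- structure ----------------
    with _stage("structure"):
        if config.run_structure and config.structure.enabled:
            sp_ = config.structure
            locus_df = _structure_locus_matrix(art["snp_matrix"])
            # duplicated genotypes (clones, replicates) violate the
            # model's no-LD assumption and inflate the likelihood of
            # spurious extra clusters; fit on the core when known
            rep_of: dict[str, str] = {}
            if "partition" in art and art["partition"].groups:
                if sp_.dedupe:
                    part = art["partition"]
                    for gid, group in enumerate(part.groups):
                        rep = part.representatives[gid]
                        for member in group:
                            if member != rep:
                                rep_of[member] = rep
                    locus_df = locus_df[art["core"]]
                else:
                    warnings.warn(
                        "redundant (clonal/replicate) lines are present: "
                        "the admixture model assumes markers not in "
                        "linkage disequilibrium, which duplicated "
                        "genotypes violate; consider dedupe=True")
            cfg = st.StructureConfig(
                k_range=(sp_.k_min, sp_.k_max), n_runs=sp_.n_runs,
                burnin=sp_.burnin, reps=sp_.reps, seed=config.seed + 6)
            runs = st.run_k_range(locus_df, cfg)
            if sp_.k_max - sp_.k_min + 1 >= 3:
                dk = st.evanno(runs)
                selected_k = dk.selected_k
                dk.table.to_csv(out_dir / "delta_k.csv")
                art["delta_k"] = dk
            else:
                selected_k = max(runs, key=lambda k: float(
                    np.mean([r.lnPD for r in runs[k]])))
            aligned = st.align_labels(runs[selected_k])
            consensus_q = np.mean([r.Q for r in aligned], axis=0)
            consensus_q /= consensus_q.sum(axis=1, keepdims=True)
            sample_ids = list(aligned[0].sample_ids)
            if rep_of:
                # redundant members inherit their representative's row
                q_by_id = {s: consensus_q[i] for i, s in enumerate(sample_ids)}
                all_ids = list(art["snp_matrix"].samples)
                consensus_q = np.vstack([
                    q_by_id[s] if s in q_by_id else q_by_id[rep_of[s]]
                    for s in all_ids])
                sample_ids = all_ids
            assignment = st.assign(consensus_q, threshold=sp_.assign_threshold,
                                   sample_ids=sample_ids)
            pd.DataFrame(consensus_q, index=sample_ids,
                         columns=[f"Q{k + 1}" for k in range(selected_k)]
                         ).to_csv(out_dir / "structure_consensus_q.csv")
            assignment.to_csv(out_dir / "structure_assignments.csv")
            report.selected_k = selected_k
            art.update(structure_runs=runs, aligned_runs=aligned,
                       consensus_q=consensus_q, assignment=assignment)

    # ---------------- concordance ----------------
    if (config.run_diversity and config.run_structure
            and config.structure.enabled and report.selected_k):
        k = report.selected_k
        tree: dv.Dendrogram = art["tree"]
        dendro_labels = dict(zip(tree.leaf_ids, tree.cut(k)))
        struct_labels = art["assignment"]["label"].to_dict()
        ordination = art["pcoa"]
        m = int(np.searchsorted(ordination.cumulative_pave, 0.95) + 1)
        m = min(max(m, 2), ordination.coordinates.shape[1], 5)
        coords = ordination.coordinates[:, :m]
        diff = coords[:, None, :] - coords[None, :, :]
        eu = np.sqrt((diff ** 2).sum(axis=2))
        scale = eu.max() or 1.0
        eu_tree = dv.hclust_complete(
            dv.DistanceMatrix(values=eu / scale, ids=ordination.ids))
        pcoa_labels = dict(zip(ordination.ids, eu_tree.cut(k)))
        report.concordance = concordance({
            "dendrogram": dendro_labels,
            "structure": struct_labels,
            "pcoa": pcoa_labels,
        })

    report.to_markdown(out_dir / "report.md")
    # wall times are informational and deliberately kept out of the
    # byte-reproducible report
    (out_dir / "stage_timings.txt").write_text(
        "".join(f"{k}\t{v}\n" for k, v in report.timings.items()))
    pd.DataFrame([{**report.accounting,
                   **{f"redundancy_{k}": v for k, v in report.redundancy.items()
                      if k != "pct_reduction_str"},
                   "selected_k": report.selected_k}]
                 ).to_csv(out_dir / "report_summary.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# truth-based evaluation (synthetic runs only)
# ---------------------------------------------------------------------------

def truth_redundancy_groups(accessions: list[sim.AccessionTruth]) -> list[set[str]]:
    """Planted identity groups: clone groups (replicates of members
    included) plus replicate pairs of non-clonal accessions."""
    groups: dict[object, set[str]] = {}
    by_id = {a.accession_id: a for a in accessions}
    for a in accessions:
        if a.clone_group is not None:
            groups.setdefault(("clone", a.clone_group), set()).add(a.accession_id)
        elif a.is_replicate_of is not None:
            src = by_id[a.is_replicate_of]
            if src.clone_group is None:
                groups.setdefault(("rep", src.accession_id), set()).update(
                    {a.accession_id, src.accession_id})
    return [g for g in groups.values() if len(g) >= 2]


def clone_group_recovery(partition: dv.RedundancyPartition,
                         accessions: list[sim.AccessionTruth]) -> dict:
    """Fraction of planted identity groups recovered exactly (group-level
    set equality against the found redundancy groups)."""
    truth = truth_redundancy_groups(accessions)
    found = {frozenset(g) for g in partition.groups}
    hit = sum(frozenset(g) in found for g in truth)
    return {"n_truth_groups": len(truth), "n_recovered": hit,
            "recovery": hit / len(truth) if truth else float("nan")}


def snp_recovery(snp_matrix: mk.MarkerMatrix, library: sim.FragmentLibrary,
                 accessions: list[sim.AccessionTruth], tag_length: int) -> dict:
    """Sensitivity and false-locus count of SNP calling against truth.

    The denominator is the *discoverable* planted variants: those whose
    minor allele is carried by at least two sequenced accessions (a
    reference-free caller cannot report a non-segregating site, and an
    allele must be seen in two samples to pass the allelic-pair
    criteria).
    """
    hap = np.array([a.haplotype for a in accessions])
    discoverable = []
    for locus in library.variant_map:
        mac = int(min(hap[:, locus].sum(), (1 - hap[:, locus]).sum()))
        if mac >= 2:
            discoverable.append(locus)
    expected = {}
    for locus in discoverable:
        pair = frozenset(sim.expected_tag_pair(library, locus, tag_length))
        expected[pair] = locus
    all_planted = {
        frozenset(sim.expected_tag_pair(library, locus, tag_length))
        for locus in library.variant_map}
    called_pairs = set()
    meta = snp_matrix.meta
    snp_meta = meta[meta["type"] == "SNP"] if "type" in meta else meta
    for _, row in snp_meta.drop_duplicates(subset=["ref_tag", "alt_tag"]).iterrows():
        called_pairs.add(frozenset((row["ref_tag"], row["alt_tag"])))
    hit = sum(pair in called_pairs for pair in expected)
    false = sum(pair not in all_planted for pair in called_pairs)
    return {
        "n_discoverable": len(expected),
        "n_recovered": hit,
        "sensitivity": hit / len(expected) if expected else float("nan"),
        "n_false_loci": false,
        "n_called_loci": len(called_pairs),
    }


def error_tag_stats(table_raw: tg.TagTable, table_groomed: tg.TagTable,
                    library: sim.FragmentLibrary,
                    accessions: list[sim.AccessionTruth],
                    tag_length: int) -> dict:
    """Tags absent from the truth fragment/allele set, before and after
    grooming (grooming should remove a large share of them)."""
    truth: set[str] = set()
    for frag in library.fragments:
        truth.add((frag.sequence + sim.ADAPTER_FILL)[:tag_length])
    for locus in library.variant_map:
        truth.update(sim.expected_tag_pair(library, locus, tag_length))

    def count_errors(table: tg.TagTable) -> int:
        return sum(1 for tags in table.tables.values()
                   for s in tags if s not in truth)

    before, after = count_errors(table_raw), count_errors(table_groomed)
    return {"error_tags_before": before, "error_tags_after": after,
            "reduction": 1.0 - after / before if before else float("nan")}


def evaluate_truth(report: RunReport) -> dict:
    """Convenience wrapper: truth-based metrics for a simulated run."""
    art = report.artifacts
    tag_length = report.accounting.get("tag_length")
    out = {}
    if "partition" in art:
        out["clones"] = clone_group_recovery(art["partition"], art["accessions"])
    if "snp_matrix" in art:
        out["snp"] = snp_recovery(art["snp_matrix"], art["library"],
                                  art["accessions"], tag_length)
    if "tag_table_raw" in art and "tag_table" in art:
        out["error_tags"] = error_tag_stats(
            art["tag_table_raw"], art["tag_table"], art["library"],
            art["accessions"], tag_length)
    return out
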