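"""From raw reads to marker matrices: demultiplex, collapse, groom, call.

Simulates a small noisy library, then runs the primary tag pipeline
(barcode split, quality filter, collapse to counted tags, grooming of
singleton tags) and the marker pipeline (threshold-3 clustering, allelic
pair parsing, presence/absence scoring, replicate-consistency filter).
"""

from pathlib import Path

from gbscore import markers as mk
from gbscore import simulate as sim
from gbscore import tags as tg

out = Path("scratch/example_02")

model = sim.simulate_populations(3, 50, fst=0.3, seed=21)
accessions = sim.simulate_accessions(model, 18, n_replicate_pairs=2, seed=22)
library = sim.digest_genome(genome_length=7_000_000, n_variants=40, n_pav=10,
                            max_fragments=70, seed=23)
manifest = sim.make_manifest(accessions, seed=24)
paths = sim.generate_reads(library, accessions, manifest, out,
                           mean_depth=20, error_rate=0.005, seed=25)

per_sample, acct = tg.demultiplex(paths["reads"], manifest)
raw = tg.collapse(per_sample, acct)
groomed = tg.groom(raw)
print(f"reads in/assigned    : {acct['reads_in']} / {acct['assigned']}")
print(f"tags before grooming : {raw.n_tags()}")
print(f"tags after grooming  : {groomed.n_tags()} "
      f"({groomed.groomed_singletons} singletons corrected)")

snp, sil = mk.call_markers(groomed)
snp, att_snp = mk.filter_markers(snp, manifest.replicate_pairs)
sil, att_sil = mk.filter_markers(sil, manifest.replicate_pairs)
print(f"SNP marker rows kept : {snp.n_markers} (attrition {att_snp})")
print(f"SilicoDArT kept      : {sil.n_markers} (attrition {att_sil})")
snp.to_csv(out / "snp_markers.csv", out / "snp_markers_meta.csv")
sil.to_csv(out / "silicodart_markers.csv", out / "silicodart_meta.csv")
# Each SNP locus contributes two presence/absence rows (one per allele);
# unpaired fragment tags yield dominant presence/absence markers.
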