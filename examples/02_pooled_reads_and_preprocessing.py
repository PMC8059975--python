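"""Pooled-progeny reads: simulation, demultiplexing and quality trimming.

One sporophyte's spore pool carries exactly two parental haplotypes; its
dual-indexed paired 2 x 250 bp reads are simulated, then routed back to the
sporophyte by the one-mismatch dual-index rule and quality-trimmed with a
10 bp sliding window at Q30.
"""

import bryoparent as bp
from bryoparent.preprocess import SampleSheet

panel = bp.simulate_panel(6, 9, seed=11)
design = bp.MesocosmDesign(female_ids=panel.females(), male_ids=panel.males(),
                           n_sporophytes=3, n_mesocosms_per_treatment=2)
truth = bp.simulate_crosses(panel, design, seed=11)
sheet = bp.make_sample_sheet(truth, seed=11)
index_of = {r.sample_id: (r.i5_index, r.i7_index) for r in sheet.itertuples()}

batches = []
for t in truth:
    reads, sidecar = bp.simulate_pool_reads(
        panel, t, depth_per_locus=100, substitution_error=0.005,
        index_pair=index_of[t.sporophyte_id], index_error_rate=0.001, seed=11,
    )
    batches.append(reads)
from bryoparent.io import ReadBatch

all_reads = ReadBatch.concat(batches)
print(f"simulated {all_reads.n} reads "
      f"({len(truth)} sporophytes x 5 loci x 100 fragments x 2 mates)")

bins, report = bp.demultiplex(all_reads, SampleSheet(sheet), max_mismatch=1)
print("\ndemultiplex report (reads per sporophyte pool):")
print(report.to_string(index=False))
print("-> 'n_mismatch_rescued' counts reads saved by the 1-mismatch rule; "
      "unmatched index pairs land in 'undetermined'")

for t in truth[:1]:
    kept, dropped = bp.trim_batch(bins[t.sporophyte_id], window=10,
                                  min_mean_q=30, min_len=50)
    shortened = int((kept.length < 250).sum())
    print(f"\ntrimming {t.sporophyte_id}: kept {kept.n} reads, "
          f"dropped {dropped}, {shortened} shortened at the 3' end")
    print("-> a read is cut at the first base of the first 10 bp window "
          "whose mean quality falls below Q30")
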