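"""Post-caller triage of SNV, indel and CNV candidates.

Each record is retained or excluded with a single primary reason code, and
proximal same-direction CNV fragments are merged before the exon-count
filter so they can jointly clear it.
"""

import cnvphylo as cp

snvs = [
    cp.SnvRecord("chr4", 55_100_000, "C", "T", tumor_vaf=0.42,
                 normal_variant_reads=0, normal_vaf=0.0, annotation="protein-coding"),
    cp.SnvRecord("chr4", 55_200_000, "G", "A", tumor_vaf=0.08,
                 normal_variant_reads=0, normal_vaf=0.0, annotation="protein-coding"),
    cp.SnvRecord("chr4", 55_300_000, "A", "C", tumor_vaf=0.35,
                 normal_variant_reads=7, normal_vaf=0.05, annotation="protein-coding"),
]
kept, reasons = cp.filter_snvs(snvs)
for rec, reason in zip(snvs, reasons):
    print(f"SNV {rec.chrom}:{rec.pos} -> {reason}")

segments = [
    cp.CnvSegment("chr7", 0, 40_000_000, n_exons=80, ratio=1.6),
    cp.CnvSegment("chr7", 40_500_000, 80_000_000, n_exons=90, ratio=1.5),
    cp.CnvSegment("chr9", 0, 30_000_000, n_exons=400, ratio=1.05),
]
retained = cp.triage_cnv_segments(segments)
for s in retained:
    print(f"CNV {s.chrom}:{s.start}-{s.end} {s.direction}, "
          f"{s.n_exons} exons, ratio {s.ratio:.2f}")
# the two chr7 gains (0.5 Mbp apart) merge to 170 exons and survive the
# >100-exon filter; the chr9 segment is neutral (0.7 <= ratio <= 1.3)
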