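"""Predict the transcripts and proteins a disrupted splice donor produces.

Uses the bundled synthetic premelanosome-protein-like gene: a 3-nt MNP
(AGT>TCC) hits the last base of exon 8 and the first two bases of the
intron-8 donor.  With the donor dead, splicing either skips exon 8 or
reads into the intron until a cryptic GT donor.
"""

from cosegmap.consequence_annot import (
    classify_coding_variant,
    enumerate_aberrant_isoforms,
    load_domain_table,
    report_truncation,
    translate_isoform,
)
from cosegmap.synthetic_genes import build_pmel_like_gene

gene = build_pmel_like_gene()
reference = gene.model.reference_protein(gene.genome)
print(f"reference transcript {gene.model.spliced_length()} nt "
      f"(second annotated isoform {gene.model_short.spliced_length()} nt), "
      f"protein {len(reference)} aa")

call = classify_coding_variant(gene.model, gene.variant, gene.genome)
print(f"variant {gene.variant.ref}>{gene.variant.alt} at the exon 8 / intron 8 "
      f"junction -> {call.category} (secondary effects: {', '.join(call.detail)})")

domains = load_domain_table()
for iso in enumerate_aberrant_isoforms(gene.model, gene.disrupted_intron, gene.genome):
    tr = translate_isoform(iso, gene.model, gene.genome)
    trunc = report_truncation(tr.protein, reference, domains)
    what = ("exon 8 skipped" if iso.kind == "exon_skip"
            else f"first {iso.retained_length} nt of intron 8 retained")
    print(f"  {what}: {len(tr.protein)} aa protein, "
          f"domains lost: {', '.join(trunc.lost) or 'none'}")
print("both retention isoforms hit the same in-frame stop inside the shared "
      "retained prefix, so they give the identical truncated protein lacking "
      "the Kringle-like domain, the transmembrane helix and the cytoplasmic tail")
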