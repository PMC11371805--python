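"""Synthetic gene fixtures for the splice-consequence machinery.

These are fully synthetic sequences (no real genome is bundled), engineered
so that the biology of interest — a donor-site disruption after exon 8 of a
premelanosome-protein-like gene — emerges from actual sequence when the
package's splice and translation code runs on it:

* the reference transcript is 3135 nt with a 2142-nt CDS (713 aa + stop),
  mirroring the annotated transcript sizes of the gene the package's worked
  examples discuss (a second annotated isoform lacking the first 3 nt of
  exon 8 gives 3132 nt);
* intron 8 begins ``GT`` and carries exactly two cryptic ``GT`` donors, at
  offsets 20 and 233, so donor disruption yields two intron-retention
  isoforms retaining 20 and 233 nt;
* both retained prefixes share an in-frame stop a few bases into the
  intron, so both retention isoforms translate to the same 532-aa
  truncated protein;
* exon 8 is 160 nt (not a multiple of 3), so the exon-skip isoform
  frameshifts into a stop at the start of exon 9, yielding a 478-aa
  protein;
* the causal lesion is a 3-nt MNP (``AGT``>``TCC``) spanning the last base
  of exon 8 and the first two bases of the donor.

All constraints are built in by construction; the numbers above are
properties of the emitted sequence, not assertions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .coseg_classifier import VariantSite
from .consequence_annot import GeneModel

__all__ = ["SyntheticGene", "build_pmel_like_gene", "reverse_complement_fixture", "write_gene_files"]

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class SyntheticGene:
    """A synthetic fixture: genome dict, gene models, and the donor MNP."""

    genome: Dict[str, str]
    model: GeneModel  # primary isoform
    model_short: GeneModel  # second isoform, first 3 nt of exon 8 missing
    variant: VariantSite  # donor-disrupting MNP
    disrupted_intron: int  # transcript-order index of the hit intron


def _codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_CODONS) for _ in range(n))


def _filler(rng: np.random.Generator, n: int) -> str:
    """Intron filler over {A, C}: guaranteed free of GT dinucleotides."""
    return "".join(rng.choice(["A", "C"]) for _ in range(n))


def build_pmel_like_gene(seed: int = 7, scaffold: str = "scaffold_tz") -> SyntheticGene:
    """Construct the premelanosome-protein-like fixture gene (plus strand)."""
    rng = np.random.default_rng(seed)

    utr5 = "".join(rng.choice(list("ACGT"), size=193))
    utr3 = "".join(rng.choice(list("ACGT"), size=800))

    # CDS layout (see module docstring): exons 1-7 carry 1434 nt (478 codons,
    # ATG first), exon 8 carries 160 nt, exon 9 the remaining 548 nt + UTR3.
    exon_cds_lengths = [150, 200, 210, 180, 220, 240, 234, 160, 548]
    seg_a = "ATG" + _codons(rng, 477)  # codons 1-478
    e8_cds = _codons(rng, 53) + "A"  # codons 479-531 + first base of codon 532
    # exon 9: 'TA' closes codon 532 (ATA); 'A' + 2 rng bases close codon 533;
    # 180 codons; final stop.  Starts 'TAA' so the exon-skip frameshift stops
    # immediately (codon 479 of the skip isoform).
    e9_cds = "TAA" + "".join(rng.choice(list("ACGT"), size=2)) + _codons(rng, 180) + "TAA"
    assert len(e8_cds) == 160 and len(e9_cds) == 548

    cds_parts: List[str] = []
    off = 0
    for L in exon_cds_lengths[:7]:
        cds_parts.append(seg_a[off : off + L])
        off += L
    cds_parts.append(e8_cds)
    cds_parts.append(e9_cds)

    # intron 8: GT..AG with an early in-frame stop (TAA at offsets 3-5 in the
    # retained prefix) and cryptic GT donors at offsets 20 and 233 only
    intron8 = (
        "GT"
        + "TAA"
        + _filler(rng, 15)  # offsets 5..19
        + "GT"  # cryptic donor at offset 20
        + _filler(rng, 211)  # offsets 22..232
        + "GT"  # cryptic donor at offset 233
        + _filler(rng, 60)
        + "AG"
    )
    assert intron8[20:22] == "GT" and intron8[233:235] == "GT"
    other_intron = lambda: "GT" + _filler(rng, 30) + "AG"  # noqa: E731

    # assemble genomic sequence
    flank = "".join(rng.choice(list("ACGT"), size=500))
    exon_seqs = [utr5 + cds_parts[0]] + cds_parts[1:8] + [cds_parts[8] + utr3]
    pieces = [flank]
    exons: List[Tuple[int, int]] = []
    cds: List[Tuple[int, int]] = []
    cursor = len(flank)
    for i, ex in enumerate(exon_seqs):
        exons.append((cursor, cursor + len(ex)))
        if i == 0:
            cds.append((cursor + len(utr5), cursor + len(ex)))
        elif i == len(exon_seqs) - 1:
            cds.append((cursor, cursor + len(cds_parts[8])))
        else:
            cds.append((cursor, cursor + len(ex)))
        pieces.append(ex)
        cursor += len(ex)
        if i < len(exon_seqs) - 1:
            intron = intron8 if i == 7 else other_intron()
            pieces.append(intron)
            cursor += len(intron)
    pieces.append("".join(rng.choice(list("ACGT"), size=500)))
    genome = {scaffold: "".join(pieces)}

    model = GeneModel(
        gene_id="PMEL_like",
        transcript_id="PMEL_like_t1",
        scaffold=scaffold,
        strand="+",
        exons=exons,
        cds=cds,
    )
    # second annotated isoform: exon 8 starts 3 nt later (in-frame)
    exons2 = list(exons)
    cds2 = list(cds)
    e8s, e8e = exons2[7]
    exons2[7] = (e8s + 3, e8e)
    cds2[7] = (e8s + 3, e8e)
    model_short = GeneModel(
        gene_id="PMEL_like",
        transcript_id="PMEL_like_t2",
        scaffold=scaffold,
        strand="+",
        exons=exons2,
        cds=cds2,
    )

    # donor MNP: last base of exon 8 (A>T) + first two intron bases (GT>CC)
    mnp_pos = exons[7][1] - 1
    variant = VariantSite(
        scaffold=scaffold,
        pos=mnp_pos,
        ref="AGT",
        alt="TCC",
        father_gt=(1, 1),
        mother_gts=[(0, 1), (0, 1)],
        homo_pool=(0, 30),
        het_pool=(15, 15),
    )
    assert genome[scaffold][mnp_pos : mnp_pos + 3] == "AGT"
    return SyntheticGene(
        genome=genome,
        model=model,
        model_short=model_short,
        variant=variant,
        disrupted_intron=7,
    )


def reverse_complement_fixture(gene: SyntheticGene) -> SyntheticGene:
    """Mirror a plus-strand fixture onto the minus strand of a flipped scaffold."""
    from .consequence_annot import revcomp

    scaffold = gene.model.scaffold
    seq = gene.genome[scaffold]
    L = len(seq)
    flipped = {scaffold: revcomp(seq)}

    def flip_blocks(blocks):
        return sorted((L - e, L - s) for s, e in blocks)

    def flip_model(m: GeneModel, suffix: str) -> GeneModel:
        return GeneModel(
            gene_id=m.gene_id,
            transcript_id=m.transcript_id + suffix,
            scaffold=scaffold,
            strand="-" if m.strand == "+" else "+",
            exons=flip_blocks(m.exons),
            cds=flip_blocks(m.cds),
        )

    v = gene.variant
    ref_rc = revcomp(v.ref)
    variant = VariantSite(
        scaffold=scaffold,
        pos=L - (v.pos + len(v.ref)),
        ref=ref_rc,
        alt=revcomp(v.alt),
        father_gt=v.father_gt,
        mother_gts=v.mother_gts,
        homo_pool=v.homo_pool,
        het_pool=v.het_pool,
    )
    return SyntheticGene(
        genome=flipped,
        model=flip_model(gene.model, "_rc"),
        model_short=flip_model(gene.model_short, "_rc"),
        variant=variant,
        disrupted_intron=gene.disrupted_intron,
    )


def write_gene_files(gene: SyntheticGene, outdir: str | Path) -> Tuple[Path, Path]:
    """Write the fixture as FASTA + GFF3 (native 1-based GFF coordinates)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "synthetic_gene.fa"
    gff = outdir / "synthetic_gene.gff3"
    with open(fasta, "w") as fh:
        for name, seq in gene.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    models = (gene.model, gene.model_short)
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        g_s = min(m.span[0] for m in models)
        g_e = max(m.span[1] for m in models)
        first = models[0]
        fh.write(
            f"{first.scaffold}\tcosegmap\tgene\t{g_s + 1}\t{g_e}\t.\t{first.strand}\t.\t"
            f"ID={first.gene_id}\n"
        )
        for model in models:
            m_s, m_e = model.span
            fh.write(
                f"{model.scaffold}\tcosegmap\tmRNA\t{m_s + 1}\t{m_e}\t.\t{model.strand}\t.\t"
                f"ID={model.transcript_id};Parent={model.gene_id}\n"
            )
            for j, (s, e) in enumerate(model.exons, 1):
                fh.write(
                    f"{model.scaffold}\tcosegmap\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t"
                    f"ID={model.transcript_id}.exon{j};Parent={model.transcript_id}\n"
                )
            phase = 0
            cds_iter = model.cds if model.strand == "+" else reversed(model.cds)
            for s, e in cds_iter:
                fh.write(
                    f"{model.scaffold}\tcosegmap\tCDS\t{s + 1}\t{e}\t.\t{model.strand}\t{phase}\t"
                    f"ID={model.transcript_id}.cds;Parent={model.transcript_id}\n"
                )
                phase = (3 - ((e - s) - phase) % 3) % 3
    return fasta, gff
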