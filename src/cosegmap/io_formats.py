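"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open throughout the package; each file
format keeps its native convention (VCF/GFF3 1-based inclusive, BED 0-based
half-open).  VCF parsing goes through cyvcf2, gene models through gffutils.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .coseg_classifier import VariantSite
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "LibrarySpec",
    "MaskSet",
    "VariantTableReader",
    "read_variant_table",
    "read_gene_models",
    "write_scan_outputs",
]

ROLES = ("father", "mother", "homo_pool", "het_pool")


@dataclass(frozen=True)
class LibrarySpec:
    """Mapping of one sequencing library to its role in the cross.

    role
        One of ``father`` (homozygous affected sire), ``mother`` (carrier
        dam; several allowed), ``homo_pool`` / ``het_pool`` (phenotype-
        sorted offspring pools).
    sample_id
        Name of the corresponding VCF sample column.
    ploidy_mode
        ``individual`` (genotype call used) or ``pool`` (allele depths used).
    pool_size
        Number of pooled individuals, pools only.
    """

    role: str
    sample_id: str
    ploidy_mode: str = "individual"
    pool_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown library role {self.role!r}")
        if self.ploidy_mode not in ("individual", "pool"):
            raise ConfigurationError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        if self.ploidy_mode == "pool" and (self.pool_size is None or self.pool_size < 1):
            raise ConfigurationError(f"pool library {self.sample_id!r} needs pool_size >= 1")


def validate_library_specs(specs: Sequence[LibrarySpec]) -> None:
    counts = {role: sum(1 for s in specs if s.role == role) for role in ROLES}
    for role in ("father", "homo_pool", "het_pool"):
        if counts[role] != 1:
            raise ConfigurationError(f"exactly one {role} library required, got {counts[role]}")
    if counts["mother"] < 1:
        raise ConfigurationError("at least one mother library required")


class MaskSet:
    """Sorted, merged set of genomic intervals (0-based half-open).

    Typically a repeat mask: sites overlapping any interval are excluded
    from co-segregation analysis.
    """

    def __init__(self, intervals: Sequence[Tuple[str, int, int]] = ()):
        per: Dict[str, List[Tuple[int, int]]] = {}
        for scaffold, start, end in intervals:
            if end <= start:
                raise ValidationError(f"empty mask interval {scaffold}:{start}-{end}")
            per.setdefault(scaffold, []).append((int(start), int(end)))
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        for scaffold, ivs in per.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[scaffold] = np.array([m[0] for m in merged])
            self._ends[scaffold] = np.array([m[1] for m in merged])

    @classmethod
    def from_bed(cls, path: str | Path) -> "MaskSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(intervals)

    @property
    def intervals(self) -> List[Tuple[str, int, int]]:
        out = []
        for scaffold in sorted(self._starts):
            for s, e in zip(self._starts[scaffold], self._ends[scaffold]):
                out.append((scaffold, int(s), int(e)))
        return out

    def overlaps(self, scaffold: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any mask interval."""
        starts = self._starts.get(scaffold)
        if starts is None:
            return False
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and self._ends[scaffold][i - 1] > start


def _gt_tuple(alleles) -> Optional[Tuple[int, int]]:
    a, b = alleles[0], alleles[1]
    if a < 0 or b < 0:
        return None
    return (int(a), int(b)) if a <= b else (int(b), int(a))


class VariantTableReader:
    """Stream biallelic sites from a VCF for a configured set of libraries.

    Iterating yields :class:`VariantSite` objects with 0-based positions.
    Multiallelic records and records overlapping the mask are dropped and
    counted in :attr:`report` (final after exhaustion).  Depths come from
    the ``AD`` FORMAT field by default; the Platypus-style ``NR``/``NV``
    dialect is selected with ``depth_field="NR/NV"``.
    """

    def __init__(
        self,
        vcf_path: str | Path,
        specs: Sequence[LibrarySpec],
        mask: Optional[MaskSet] = None,
        depth_field: str = "AD",
    ):
        import cyvcf2

        validate_library_specs(specs)
        if depth_field not in ("AD", "NR/NV"):
            raise ConfigurationError(f"unknown depth_field {depth_field!r}")
        self._vcf = cyvcf2.VCF(str(vcf_path))
        self._mask = mask
        self._depth_field = depth_field
        samples = list(self._vcf.samples)
        for spec in specs:
            if spec.sample_id not in samples:
                raise ConfigurationError(
                    f"sample {spec.sample_id!r} ({spec.role}) not in VCF columns {samples}"
                )
        idx = {s: samples.index(s) for s in (spec.sample_id for spec in specs)}
        self._father = next(idx[s.sample_id] for s in specs if s.role == "father")
        self._mothers = [idx[s.sample_id] for s in specs if s.role == "mother"]
        self._homo = next(idx[s.sample_id] for s in specs if s.role == "homo_pool")
        self._het = next(idx[s.sample_id] for s in specs if s.role == "het_pool")
        self.report = {"yielded": 0, "multiallelic_dropped": 0, "masked_dropped": 0}
        self.contig_lengths: Dict[str, int] = {}
        for name, length in zip(self._vcf.seqnames, self._vcf.seqlens or []):
            self.contig_lengths[name] = length

    def _depths(self, record) -> Optional[np.ndarray]:
        """(n_samples, 2) ref/alt depths, or None when the field is absent."""
        if self._depth_field == "AD":
            ad = record.format("AD")
            if ad is None:
                return None
            ad = np.asarray(ad)
            if ad.ndim == 1 or ad.shape[1] < 2:
                return None
            return np.maximum(ad[:, :2], 0)
        nr = record.format("NR")
        nv = record.format("NV")
        if nr is None or nv is None:
            return None
        nr = np.maximum(np.asarray(nr)[:, 0], 0)
        nv = np.maximum(np.asarray(nv)[:, 0], 0)
        return np.stack([nr - nv, nv], axis=1)

    def __iter__(self) -> Iterator[VariantSite]:
        for record in self._vcf:
            if len(record.ALT) != 1:
                self.report["multiallelic_dropped"] += 1
                continue
            pos0 = record.POS - 1
            ref, alt = record.REF, record.ALT[0]
            if self._mask is not None and self._mask.overlaps(
                record.CHROM, pos0, pos0 + len(ref)
            ):
                self.report["masked_dropped"] += 1
                continue
            gts = record.genotypes
            depths = self._depths(record)
            if depths is None:
                homo_pool = het_pool = None
                father_dp = None
                mother_dps = [None] * len(self._mothers)
            else:
                homo_pool = (int(depths[self._homo, 0]), int(depths[self._homo, 1]))
                het_pool = (int(depths[self._het, 0]), int(depths[self._het, 1]))
                father_dp = int(depths[self._father].sum())
                mother_dps = [int(depths[m].sum()) for m in self._mothers]
            self.report["yielded"] += 1
            yield VariantSite(
                scaffold=record.CHROM,
                pos=pos0,
                ref=ref,
                alt=alt,
                father_gt=_gt_tuple(gts[self._father]),
                mother_gts=[_gt_tuple(gts[m]) for m in self._mothers],
                homo_pool=homo_pool,
                het_pool=het_pool,
                father_depth=father_dp,
                mother_depths=mother_dps,
            )


def read_variant_table(
    vcf_path: str | Path,
    specs: Sequence[LibrarySpec],
    mask: Optional[MaskSet] = None,
    depth_field: str = "AD",
) -> VariantTableReader:
    """Open a VCF as a stream of biallelic :class:`VariantSite` records."""
    return VariantTableReader(vcf_path, specs, mask=mask, depth_field=depth_field)


def read_gene_models(gff_path: str | Path):
    """Parse GFF3 gene models into :class:`~cosegmap.consequence_annot.GeneModel`.

    Exons are kept in transcription order (5'->3' on the transcript);
    genomic coordinates are converted to 0-based half-open.
    """
    import gffutils

    from .consequence_annot import GeneModel

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for mrna in db.features_of_type("mRNA"):
        exons = []
        cds = []
        for exon in db.children(mrna, featuretype="exon", order_by="start"):
            if exon.start < mrna.start or exon.end > mrna.end:
                raise ValidationError(
                    f"exon {exon.id!r} outside its mRNA span ({mrna.id})"
                )
            exons.append((exon.start - 1, exon.end))
        for c in db.children(mrna, featuretype="CDS", order_by="start"):
            cds.append((c.start - 1, c.end))
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                scaffold=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
                protein_id=mrna.attributes.get("protein_id", [""])[0],
            )
        )
    return models


def write_scan_outputs(
    windows,
    out_prefix: str | Path,
    bed_min_proportion: float = 0.9,
) -> Tuple[Path, Path]:
    """Write windows as a TSV plus a BED of above-threshold windows.

    The TSV reports 1-based inclusive coordinates; the BED keeps its native
    0-based half-open convention.  Windows with no informative site
    serialise their proportion as ``NA`` and never reach the BED.  Ordering
    follows the input (scaffold appearance order, then start), so repeated
    runs on identical input are byte-identical.
    """
    windows = list(windows)
    if not windows:
        raise ValidationError("no windows to write")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = out_prefix.with_suffix(".windows.tsv")
    bed = out_prefix.with_suffix(".windows.bed")
    with open(tsv, "w") as fh:
        fh.write("scaffold\tstart\tend\tn_informative\tn_coseg\tproportion\n")
        for w in windows:
            prop = "NA" if w.proportion is None else f"{w.proportion:.6g}"
            fh.write(
                f"{w.scaffold}\t{w.start + 1}\t{w.end}\t{w.n_informative}\t{w.n_coseg}\t{prop}\n"
            )
    with open(bed, "w") as fh:
        for w in windows:
            if w.proportion is not None and w.proportion >= bed_min_proportion:
                fh.write(f"{w.scaffold}\t{w.start}\t{w.end}\t{w.proportion:.6g}\n")
    return tsv, bed
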