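"""Crossover breakpoint calling from per-marker allele depths.

Recombinant F2 seeds preselected by single-colour fluorescence carry one
recombinant chromatid over a non-recombinant Ler homolog, so across the
interval each recombinant is homozygous Ler on one side of its crossover
and Col/Ler heterozygous on the other. Genotypes are called per marker
from the read depths supporting the two parental alleles, segmented into
haplotype blocks, and the crossover is localized to the gap between the
two adjacent informative markers flanking the single block boundary.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "Orientation",
    "CallStatus",
    "Marker",
    "SnpMap",
    "MarkerSupport",
    "AlleleDepthTable",
    "GenotypeTrack",
    "CrossoverCall",
    "filter_snp_candidates",
    "call_site_genotypes",
    "call_crossover",
    "map_population",
    "read_snp_map_tsv",
    "write_snp_map_tsv",
    "read_snp_map_vcf",
    "write_snp_map_vcf",
    "read_depth_tables",
    "write_depth_tables",
    "write_crossover_bed",
    "read_crossover_bed",
]

_BASES = frozenset("ACGT")


class Genotype(enum.IntEnum):
    HOM_LER = 0
    HET = 1
    HOM_COL = 2
    MISSING = 3


class Orientation(str, enum.Enum):
    """Which side of the breakpoint is homozygous Ler.

    ``LER_TO_HET``: Ler block left of the crossover, heterozygous right
    (the green-only seed class); ``HET_TO_LER`` is the reciprocal
    (red-only).
    """

    LER_TO_HET = "LER_TO_HET"
    HET_TO_LER = "HET_TO_LER"


class CallStatus(str, enum.Enum):
    OK = "OK"
    NO_TRANSITION = "NO_TRANSITION"
    MULTIPLE_TRANSITIONS = "MULTIPLE_TRANSITIONS"
    UNEXPECTED_GENOTYPE = "UNEXPECTED_GENOTYPE"


@dataclass(frozen=True)
class Marker:
    """One biallelic Col/Ler SNP marker (1-based position)."""

    position: int
    col_allele: str
    ler_allele: str
    id: str

    def __post_init__(self) -> None:
        if self.col_allele not in _BASES or self.ler_allele not in _BASES:
            raise ValueError(f"marker {self.id}: alleles must be A/C/G/T")
        if self.col_allele == self.ler_allele:
            raise ValueError(f"marker {self.id}: alleles must differ")


@dataclass(frozen=True)
class SnpMap:
    """Ordered biallelic markers over one genomic interval."""

    interval_name: str
    chrom: str
    start: int  # 1-based inclusive span of the interval
    end: int
    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")
        pos = [m.position for m in self.markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("marker positions must be strictly increasing")
        if pos and (pos[0] < self.start or pos[-1] > self.end):
            raise ValueError("marker positions must lie within the interval span")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position for m in self.markers], dtype=np.int64)

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MarkerSupport:
    """A candidate marker with its homozygous-control support statistics.

    ``n_concordant`` of ``n_obs`` control observations showed the declared
    parental allele at this site.
    """

    position: int
    col_allele: str
    ler_allele: str
    id: str
    n_obs: int
    n_concordant: int


@dataclass
class AlleleDepthTable:
    """Per-marker read depths for one recombinant, aligned to a SnpMap."""

    recombinant_id: str
    marker_ids: list[str]
    depth_col: np.ndarray
    depth_ler: np.ndarray

    def __post_init__(self) -> None:
        self.depth_col = np.asarray(self.depth_col, dtype=np.int64)
        self.depth_ler = np.asarray(self.depth_ler, dtype=np.int64)
        n = len(self.marker_ids)
        if self.depth_col.shape != (n,) or self.depth_ler.shape != (n,):
            raise ValueError("depth arrays must match the marker list length")
        if (self.depth_col < 0).any() or (self.depth_ler < 0).any():
            raise ValueError("depths must be non-negative")


@dataclass
class GenotypeTrack:
    """Per-marker genotype calls for one recombinant."""

    recombinant_id: str
    positions: np.ndarray
    calls: np.ndarray  # Genotype codes, int8
    col_fraction: np.ndarray  # NaN where total depth is 0
    marker_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CrossoverCall:
    """Breakpoint interval between flanking informative markers.

    Positions are 1-based marker coordinates; the crossover is localized
    to the open gap between ``left_pos`` and ``right_pos``. The midpoint
    is ``floor((left_pos + right_pos) / 2)`` and lies strictly inside the
    gap whenever the gap spans at least 2 bp.
    """

    recombinant_id: str
    status: CallStatus
    chrom: str = "."
    left_pos: int | None = None
    right_pos: int | None = None
    left_id: str | None = None
    right_id: str | None = None
    midpoint: int | None = None
    orientation: Orientation | None = None


# ---------------------------------------------------------------------------
# Marker filtering


def filter_snp_candidates(
    candidates: list[MarkerSupport],
    min_support: float = 0.9,
    interval_name: str = "interval",
    chrom: str = ".",
    start: int | None = None,
    end: int | None = None,
) -> SnpMap:
    """Retain high-fidelity markers from control support statistics.

    A candidate is kept when it is biallelic (Col allele differs from Ler
    allele) and the declared parental alleles were confirmed in at least
    ``min_support`` of homozygous control observations. Sites without any
    control observation cannot be validated and are dropped.
    """
    pos = [c.position for c in candidates]
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise ValueError("candidates must be sorted by strictly increasing position")
    kept = []
    for c in candidates:
        if c.col_allele == c.ler_allele:
            continue
        if c.n_obs <= 0:
            continue
        if c.n_concordant / c.n_obs >= min_support:
            kept.append(Marker(c.position, c.col_allele, c.ler_allele, c.id))
    if not kept:
        warnings.warn("no candidate markers passed filtering", stacklevel=2)
    lo = start if start is not None else (kept[0].position if kept else 1)
    hi = end if end is not None else (kept[-1].position if kept else 2)
    return SnpMap(interval_name, chrom, lo, max(hi, lo + 1), tuple(kept))


# ---------------------------------------------------------------------------
# Genotype and crossover calling


def call_site_genotypes(
    depths: AlleleDepthTable,
    snps: SnpMap,
    min_depth: int = 20,
    het_band: tuple[float, float] = (0.30, 0.70),
    hom_max: float = 0.15,
) -> GenotypeTrack:
    """Call HOM_LER / HET / HOM_COL / MISSING per marker from allele depths.

    Markers with total depth below ``min_depth`` are MISSING. Otherwise
    the Col-supporting read fraction decides: at most ``hom_max`` is
    HOM_LER, within ``het_band`` (inclusive) is HET, at least
    ``1 - hom_max`` is HOM_COL, and anything between the bands is
    ambiguous, hence MISSING.
    """
    if depths.marker_ids != snps.marker_ids:
        raise ValueError("depth table markers must match the SNP map")
    if not (0.0 <= hom_max < het_band[0] <= het_band[1] < 1.0 - hom_max):
        raise ValueError("thresholds must satisfy hom_max < het_lo <= het_hi < 1-hom_max")
    total = depths.depth_col + depths.depth_ler
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, depths.depth_col / np.maximum(total, 1), np.nan)
    calls = np.full(len(total), Genotype.MISSING, dtype=np.int8)
    ok = total >= min_depth
    calls[ok & (frac <= hom_max)] = Genotype.HOM_LER
    calls[ok & (frac >= het_band[0]) & (frac <= het_band[1])] = Genotype.HET
    calls[ok & (frac >= 1.0 - hom_max)] = Genotype.HOM_COL
    return GenotypeTrack(
        recombinant_id=depths.recombinant_id,
        positions=snps.positions,
        calls=calls,
        col_fraction=frac,
        marker_ids=list(snps.marker_ids),
    )


def call_crossover(
    track: GenotypeTrack,
    min_flank: int = 2,
    chrom: str = ".",
) -> CrossoverCall:
    """Localize one crossover from a recombinant's genotype track.

    Informative (non-MISSING) calls are segmented into maximal runs of
    identical genotype. Exactly one HOM_LER/HET boundary with at least
    ``min_flank`` concordant markers on each side yields status OK and a
    breakpoint interval spanning the two flanking markers. Any HOM_COL
    call is a QC failure (UNEXPECTED_GENOTYPE): these chromatids cannot
    arise from a single crossover over a Ler homolog. More than one
    boundary is MULTIPLE_TRANSITIONS; zero boundaries, or a single
    boundary with insufficient flanking support, is NO_TRANSITION.
    """
    informative = track.calls != Genotype.MISSING
    if int(informative.sum()) < 2:
        raise ValueError(
            f"{track.recombinant_id}: need at least 2 informative markers"
        )
    geno = track.calls[informative]
    pos = track.positions[informative]
    ids = [m for m, keep in zip(track.marker_ids, informative) if keep] if track.marker_ids else [""] * len(pos)

    if (geno == Genotype.HOM_COL).any():
        return CrossoverCall(track.recombinant_id, CallStatus.UNEXPECTED_GENOTYPE, chrom)

    boundaries = np.flatnonzero(geno[:-1] != geno[1:])
    if boundaries.size == 0:
        return CrossoverCall(track.recombinant_id, CallStatus.NO_TRANSITION, chrom)
    if boundaries.size > 1:
        return CrossoverCall(track.recombinant_id, CallStatus.MULTIPLE_TRANSITIONS, chrom)

    i = int(boundaries[0])  # boundary between informative markers i and i+1
    left_n = i + 1
    right_n = len(geno) - left_n
    if left_n < min_flank or right_n < min_flank:
        return CrossoverCall(track.recombinant_id, CallStatus.NO_TRANSITION, chrom)

    orientation = (
        Orientation.LER_TO_HET if geno[0] == Genotype.HOM_LER else Orientation.HET_TO_LER
    )
    left_pos, right_pos = int(pos[i]), int(pos[i + 1])
    return CrossoverCall(
        recombinant_id=track.recombinant_id,
        status=CallStatus.OK,
        chrom=chrom,
        left_pos=left_pos,
        right_pos=right_pos,
        left_id=ids[i],
        right_id=ids[i + 1],
        midpoint=(left_pos + right_pos) // 2,
        orientation=orientation,
    )


def map_population(
    tables: list[AlleleDepthTable],
    snps: SnpMap,
    min_depth: int = 20,
    het_band: tuple[float, float] = (0.30, 0.70),
    hom_max: float = 0.15,
    min_flank: int = 2,
) -> tuple[list[CrossoverCall], Counter]:
    """Call crossovers for a whole recombinant population.

    Returns one CrossoverCall per input table plus a tally of statuses.
    Only OK calls should feed landscape construction.
    """
    calls: list[CrossoverCall] = []
    tally: Counter = Counter()
    for table in tables:
        track = call_site_genotypes(
            table, snps, min_depth=min_depth, het_band=het_band, hom_max=hom_max
        )
        if int((track.calls != Genotype.MISSING).sum()) < 2:
            # too little usable depth to segment at all
            call = CrossoverCall(
                table.recombinant_id, CallStatus.NO_TRANSITION, snps.chrom
            )
        else:
            call = call_crossover(track, min_flank=min_flank, chrom=snps.chrom)
        calls.append(call)
        tally[call.status] += 1
    return calls, tally


# ---------------------------------------------------------------------------
# SnpMap I/O: 4-column TSV dialect and VCF


def write_snp_map_tsv(snps: SnpMap, path) -> None:
    """Write the 4-column marker TSV with the interval span in the header."""
    with open(path, "w") as fh:
        fh.write(f"#interval_name={snps.interval_name}\n")
        fh.write(f"#chrom={snps.chrom}\n")
        fh.write(f"#span={snps.start}-{snps.end}\n")
        fh.write("position\tcol_allele\tler_allele\tid\n")
        for m in snps.markers:
            fh.write(f"{m.position}\t{m.col_allele}\t{m.ler_allele}\t{m.id}\n")


def read_snp_map_tsv(path) -> SnpMap:
    meta = {}
    markers = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
                continue
            if line.startswith("position\t") or not line:
                continue
            p, col, ler, mid = line.split("\t")
            markers.append(Marker(int(p), col, ler, mid))
    start, _, end = meta.get("span", "").partition("-")
    return SnpMap(
        interval_name=meta.get("interval_name", "interval"),
        chrom=meta.get("chrom", "."),
        start=int(start) if start else (markers[0].position if markers else 1),
        end=int(end) if end else (markers[-1].position if markers else 2),
        markers=tuple(markers),
    )


def write_snp_map_vcf(snps: SnpMap, path) -> None:
    """Write markers as a biallelic-SNP VCF (Col as REF, Ler as ALT)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={snps.chrom},length={snps.end}>")
    header.add_line(f'##xomap_interval=<Name={snps.interval_name},Start={snps.start},End={snps.end}>')
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for m in snps.markers:
            rec = vcf.new_record(
                contig=snps.chrom,
                start=m.position - 1,
                stop=m.position,
                alleles=(m.col_allele, m.ler_allele),
                id=m.id,
            )
            vcf.write(rec)


def read_snp_map_vcf(path, interval_name: str | None = None) -> SnpMap:
    import pysam

    markers = []
    chrom = "."
    start = end = None
    name = interval_name or "interval"
    with pysam.VariantFile(str(path)) as vcf:
        for line in str(vcf.header).splitlines():
            if line.startswith("##xomap_interval="):
                body = line.split("=", 1)[1].strip("<>")
                fields = dict(kv.split("=") for kv in body.split(","))
                name = interval_name or fields.get("Name", name)
                start = int(fields["Start"])
                end = int(fields["End"])
        for rec in vcf:
            chrom = rec.chrom
            if len(rec.alts or ()) != 1:
                raise ValueError(f"marker {rec.id}: VCF records must be biallelic")
            markers.append(
                Marker(rec.pos, rec.ref, rec.alts[0], rec.id or f"m{rec.pos}")
            )
    if start is None:
        start = markers[0].position if markers else 1
        end = markers[-1].position if markers else 2
    return SnpMap(name, chrom, start, end, tuple(markers))


# ---------------------------------------------------------------------------
# Allele-depth and crossover I/O


def write_depth_tables(tables: list[AlleleDepthTable], path) -> None:
    """Write long-format depth TSV: recombinant_id, marker_id, depths."""
    frames = [
        pd.DataFrame(
            dict(
                recombinant_id=t.recombinant_id,
                marker_id=t.marker_ids,
                depth_col=t.depth_col,
                depth_ler=t.depth_ler,
            )
        )
        for t in tables
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_depth_tables(path, snps: SnpMap) -> list[AlleleDepthTable]:
    """Read long-format depth TSV and align each recombinant to the map.

    Markers absent from a recombinant's rows get zero depth (MISSING
    downstream); rows for markers not in the map are an error.
    """
    df = pd.read_csv(path, sep="\t")
    idx = {mid: k for k, mid in enumerate(snps.marker_ids)}
    unknown = set(df["marker_id"].astype(str)) - set(idx)
    if unknown:
        raise ValueError(f"depth table references unknown markers: {sorted(unknown)[:5]}")
    tables = []
    for rid, sub in df.groupby("recombinant_id", sort=False):
        dc = np.zeros(len(snps), dtype=np.int64)
        dl = np.zeros(len(snps), dtype=np.int64)
        rows = [idx[m] for m in sub["marker_id"].astype(str)]
        dc[rows] = sub["depth_col"].to_numpy()
        dl[rows] = sub["depth_ler"].to_numpy()
        tables.append(AlleleDepthTable(str(rid), list(snps.marker_ids), dc, dl))
    return tables


def write_crossover_bed(calls: list[CrossoverCall], path) -> None:
    """BED-like TSV of breakpoint intervals, 0-based half-open.

    The 1-based open gap (left_pos, right_pos) maps to the 0-based
    half-open interval [left_pos, right_pos). Non-OK calls are written
    with '.' coordinates so the per-recombinant outcome is preserved.
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\trecombinant_id\torientation\tstatus\n")
        for c in calls:
            if c.status is CallStatus.OK:
                fh.write(
                    f"{c.chrom}\t{c.left_pos}\t{c.right_pos}\t{c.recombinant_id}"
                    f"\t{c.orientation.value}\t{c.status.value}\n"
                )
            else:
                fh.write(f"{c.chrom}\t.\t.\t{c.recombinant_id}\t.\t{c.status.value}\n")


def read_crossover_bed(path) -> list[CrossoverCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, s, e, rid, ori, status = line.rstrip("\n").split("\t")
            st = CallStatus(status)
            if st is CallStatus.OK:
                left, right = int(s), int(e)
                calls.append(
                    CrossoverCall(
                        recombinant_id=rid,
                        status=st,
                        chrom=chrom,
                        left_pos=left,
                        right_pos=right,
                        midpoint=(left + right) // 2,
                        orientation=Orientation(ori),
                    )
                )
            else:
                calls.append(CrossoverCall(recombinant_id=rid, status=st, chrom=chrom))
    return calls
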