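"""Cytoband-anchored virtual-probe grid and within-band K-NN resampling.

aCGH cohorts collected on heterogeneous platforms do not share probe
positions. To compare samples jointly, every profile is resampled onto a
common *virtual grid*: each retained cytogenetic band is subdivided into
``n_per_band`` equal slots, and the value at each slot is the mean of the
K nearest real probes *inside the same band*. Resampling never mixes
probes across band boundaries, so band-level structure is preserved.

Coordinates are 0-based, half-open everywhere (the UCSC cytoBand
convention). Bands on the acrocentric short arms 13p, 14p, 15p and 22p
and on the sex chromosomes are excluded by default; only autosomes 1-22
are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_ARMS = frozenset({"13p", "14p", "15p", "22p"})
DEFAULT_RETAINED_CHROMOSOMES = frozenset(str(c) for c in range(1, 23))


def _norm_chrom(label: str) -> str:
    """Strip a leading 'chr' prefix: 'chr17' and '17' both -> '17'."""
    label = str(label).strip()
    return label[3:] if label.lower().startswith("chr") else label


@dataclass(frozen=True)
class Band:
    chrom: str          # normalized label, e.g. "17"
    start: int          # 0-based inclusive
    end: int            # exclusive
    name: str           # e.g. "q21.3"
    stain: str          # gieStain value

    @property
    def arm(self) -> str:
        """'p' or 'q', from the band-name prefix."""
        arm = self.name[:1]
        if arm not in ("p", "q"):
            raise ValueError(f"cannot assign arm for band name {self.name!r}")
        return arm


@dataclass
class CytobandMap:
    """Ordered, non-overlapping cytogenetic bands with centromere positions.

    ``centromeres`` maps chromosome -> genomic bp of the boundary between
    the two acen-stained bands (p/q junction). Chromosomes whose p arm was
    filtered out still carry a centromere when at least one acen band
    survives in the raw file used to build the map.
    """

    bands: list[Band]
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_chrom: dict[str, list[Band]] = {}
        for b in self.bands:
            if b.end <= b.start:
                raise ValueError(f"band {b.chrom}{b.name}: end {b.end} <= start {b.start}")
            by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, bs in by_chrom.items():
            for prev, cur in zip(bs, bs[1:]):
                if cur.start < prev.start:
                    raise ValueError(f"bands on chr{chrom} are not sorted by start")
                if cur.start < prev.end:
                    raise ValueError(
                        f"overlapping bands on chr{chrom}: "
                        f"{prev.name} [{prev.start},{prev.end}) and {cur.name} [{cur.start},{cur.end})"
                    )

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.bands:
            seen.setdefault(b.chrom, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.bands)


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def read_cytobands(
    path: str | Path,
    excluded_arms: Iterable[str] = DEFAULT_EXCLUDED_ARMS,
    retained_chromosomes: Iterable[str] = DEFAULT_RETAINED_CHROMOSOMES,
) -> CytobandMap:
    """Parse a UCSC cytoBand.txt file into a filtered :class:`CytobandMap`.

    Parameters
    ----------
    path
        Tab-separated file with columns chrom, chromStart, chromEnd, name,
        gieStain (no header), 0-based half-open coordinates.
    excluded_arms
        Chromosome-arm labels like ``"13p"`` whose bands are dropped.
    retained_chromosomes
        Normalized chromosome labels kept (default: autosomes 1-22).

    Centromeres are located before arm/chromosome filtering, at the
    boundary between the two acen-stained bands of each chromosome.
    """
    excluded_arms = {a.lower() for a in excluded_arms}
    retained = {_norm_chrom(c) for c in retained_chromosomes}

    raw: list[Band] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(
                    f"{path}: line {lineno}: expected 5 tab-separated fields, got {len(fields)}"
                )
            chrom, start_s, end_s, name, stain = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            raw.append(Band(_norm_chrom(chrom), start, end, name, stain))

    if not raw:
        raise ValueError(f"{path}: no cytoband entries found")

    # Centromere = junction of the two acen bands (the only annotation the
    # cytoBand format provides). Taken on the unfiltered file so that
    # chromosomes losing their whole p arm still get a position.
    centromeres: dict[str, int] = {}
    for chrom in {b.chrom for b in raw}:
        acen = sorted((b for b in raw if b.chrom == chrom and b.stain == "acen"),
                      key=lambda b: b.start)
        if len(acen) == 2 and acen[0].end == acen[1].start:
            centromeres[chrom] = acen[0].end
        elif acen:
            centromeres[chrom] = acen[0].end

    kept = [
        b for b in raw
        if b.chrom in retained and f"{b.chrom}{b.arm}" not in excluded_arms
    ]
    kept.sort(key=lambda b: (_chrom_sort_key(b.chrom), b.start))
    centromeres = {c: pos for c, pos in centromeres.items() if c in {b.chrom for b in kept}}
    return CytobandMap(bands=kept, centromeres=centromeres)


@dataclass(frozen=True)
class VirtualProbe:
    chrom: str
    band_index: int     # index into CytobandMap.bands
    position: int       # genomic bp, midpoint of its slot
    slot: int           # 0 .. n_per_band-1 within the band


@dataclass
class VirtualGrid:
    """Virtual probes: ``n_per_band`` per retained band, globally ordered.

    ``boundary`` has one flag per adjacent probe pair (length L-1); True
    where the pair spans a chromosome boundary or the centromere (p/q arm
    change). Total-variation weights are zeroed at flagged positions so
    the fused penalty never couples across chromosomes or arms.
    """

    bands: CytobandMap
    n_per_band: int
    probes: list[VirtualProbe]
    boundary: np.ndarray  # bool, length L-1

    @property
    def L(self) -> int:
        return len(self.probes)

    def band_of_probe(self) -> np.ndarray:
        return np.array([p.band_index for p in self.probes])

    def probes_of_band(self, band_index: int) -> slice:
        i0 = band_index * self.n_per_band
        return slice(i0, i0 + self.n_per_band)

    def to_json(self) -> dict:
        return {
            "n_per_band": self.n_per_band,
            "bands": [
                {"chrom": b.chrom, "start": b.start, "end": b.end,
                 "name": b.name, "stain": b.stain}
                for b in self.bands.bands
            ],
            "centromeres": self.bands.centromeres,
        }

    @classmethod
    def from_json(cls, doc: dict) -> "VirtualGrid":
        bands = CytobandMap(
            bands=[Band(d["chrom"], d["start"], d["end"], d["name"], d["stain"])
                   for d in doc["bands"]],
            centromeres={k: int(v) for k, v in doc.get("centromeres", {}).items()},
        )
        return build_virtual_grid(bands, n_per_band=doc["n_per_band"])


def build_virtual_grid(bands: CytobandMap, n_per_band: int = 10) -> VirtualGrid:
    """Subdivide each band into ``n_per_band`` equal slots; probe = slot midpoint.

    A band [start, end) yields positions start + (i + 1/2) * (end-start)/N
    for i = 0..N-1 (integer-rounded, strictly increasing). Boundary flags
    mark adjacent probe pairs that change chromosome or arm.
    """
    if n_per_band < 1:
        raise ValueError("n_per_band must be >= 1")
    if len(bands) == 0:
        raise ValueError("empty CytobandMap")

    probes: list[VirtualProbe] = []
    for bi, band in enumerate(bands.bands):
        width = (band.end - band.start) / n_per_band
        for slot in range(n_per_band):
            pos = band.start + (slot + 0.5) * width
            probes.append(VirtualProbe(band.chrom, bi, int(pos), slot))

    flags = np.zeros(len(probes) - 1, dtype=bool) if len(probes) > 1 else np.zeros(0, dtype=bool)
    for i in range(len(probes) - 1):
        a, b = probes[i], probes[i + 1]
        ba, bb = bands.bands[a.band_index], bands.bands[b.band_index]
        if a.chrom != b.chrom or ba.arm != bb.arm:
            flags[i] = True
    return VirtualGrid(bands=bands, n_per_band=n_per_band, probes=probes, boundary=flags)


@dataclass
class ProbeProfile:
    """One sample's real probes: id, chromosome, position, log2-ratio."""

    sample_id: str
    probe_ids: list[str]
    chrom: np.ndarray      # object array of normalized labels
    position: np.ndarray   # int
    log2: np.ndarray       # float

    def __post_init__(self) -> None:
        if np.any(self.position < 0):
            raise ValueError("probe positions must be nonnegative")
        n = len(self.position)
        if not (len(self.chrom) == n == len(self.log2) == len(self.probe_ids)):
            raise ValueError("probe field lengths differ")


def knn_resample(
    profile: ProbeProfile,
    grid: VirtualGrid,
    k: int = 10,
    impute_value: float = 0.0,
) -> np.ndarray:
    """Resample a probe-level profile onto the virtual grid by within-band K-NN.

    Each virtual probe takes the unweighted mean of the min(k, m) real
    probes nearest to it in genomic distance among the m real probes of
    its own band (half-open membership [start, end)). Ties at the cut
    distance are all included, so the average can use more than k probes
    but never depends on input order. Bands with no real probe are
    imputed with ``impute_value`` (neutral log-ratio 0 by default) and
    logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = np.empty(grid.L)
    chrom_arr = profile.chrom.astype(object)

    covered_chroms = set(chrom_arr.tolist())
    for chrom in grid.bands.chromosomes:
        if chrom not in covered_chroms:
            logger.warning("sample %s: no probes on retained chromosome %s; imputing",
                           profile.sample_id, chrom)

    n_missing_bands = 0
    for bi, band in enumerate(grid.bands.bands):
        sel = (chrom_arr == band.chrom) & (profile.position >= band.start) & (profile.position < band.end)
        pos_in = profile.position[sel]
        val_in = profile.log2[sel]
        sl = grid.probes_of_band(bi)
        if pos_in.size == 0:
            out[sl] = impute_value
            n_missing_bands += 1
            continue
        vpos = np.array([p.position for p in grid.probes[sl]])
        # distances: (n_virtual, m_real)
        d = np.abs(vpos[:, None] - pos_in[None, :])
        kk = min(k, pos_in.size)
        for vi in range(d.shape[0]):
            dv = d[vi]
            cut = np.partition(dv, kk - 1)[kk - 1]
            take = dv <= cut  # include all ties at the cut distance
            out[sl.start + vi] = val_in[take].mean()
    if n_missing_bands:
        logger.info("sample %s: %d/%d bands had no probes; imputed %.3g",
                    profile.sample_id, n_missing_bands, len(grid.bands), impute_value)
    return out


@dataclass
class CohortMatrix:
    """S samples x L virtual probes of log2-ratios on a shared grid."""

    Y: np.ndarray               # (S, L)
    sample_ids: list[str]
    grid: VirtualGrid

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-D (samples x probes)")
        if self.Y.shape[0] != len(self.sample_ids):
            raise ValueError("row count != number of sample ids")
        if self.Y.shape[1] != self.grid.L:
            raise ValueError(f"Y has {self.Y.shape[1]} columns but grid has L={self.grid.L}")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("CohortMatrix contains non-finite values after imputation")

    @property
    def S(self) -> int:
        return self.Y.shape[0]

    @property
    def L(self) -> int:
        return self.Y.shape[1]

    def subset(self, sample_ids: Sequence[str]) -> "CohortMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CohortMatrix(self.Y[idx], list(sample_ids), self.grid)


def assemble_cohort(
    aligned: Sequence[np.ndarray],
    sample_ids: Sequence[str],
    grid: VirtualGrid,
) -> CohortMatrix:
    """Stack aligned vectors into a CohortMatrix, in the given sample order.

    No z-score or other per-sample standardization is applied: resampled
    log-ratios enter the model on their native scale.
    """
    if len(aligned) != len(sample_ids):
        raise ValueError("number of vectors != number of sample ids")
    vecs = []
    for sid, v in zip(sample_ids, aligned):
        v = np.asarray(v, dtype=float)
        if v.shape != (grid.L,):
            raise ValueError(f"sample {sid}: vector length {v.shape} != grid L={grid.L}")
        vecs.append(v)
    return CohortMatrix(np.vstack(vecs) if vecs else np.zeros((0, grid.L)),
                        list(sample_ids), grid)


# ---------------------------------------------------------------------------
# File I/O: probe maps, log-ratio matrices, cohort round-trip
# ---------------------------------------------------------------------------

def read_probe_profiles(probe_map_tsv: str | Path, logratio_tsv: str | Path) -> list[ProbeProfile]:
    """Read probe-level profiles from a probe map and a probes x samples matrix.

    The probe map has columns ``probe_id``, ``chrom``, ``pos``; the
    log-ratio matrix is TSV with a ``probe_id`` index column and one
    column per sample.
    """
    pmap = pd.read_csv(probe_map_tsv, sep="\t", dtype={"probe_id": str, "chrom": str})
    for col in ("probe_id", "chrom", "pos"):
        if col not in pmap.columns:
            raise ValueError(f"probe map missing column {col!r}")
    mat = pd.read_csv(logratio_tsv, sep="\t", index_col=0)
    mat = mat.loc[pmap["probe_id"].values]
    chrom = pmap["chrom"].map(_norm_chrom).to_numpy(dtype=object)
    pos = pmap["pos"].to_numpy(dtype=int)
    return [
        ProbeProfile(sample_id=str(sid), probe_ids=pmap["probe_id"].tolist(),
                     chrom=chrom, position=pos, log2=mat[sid].to_numpy(dtype=float))
        for sid in mat.columns
    ]


def write_cohort(cohort: CohortMatrix, tsv_path: str | Path, sidecar_json: str | Path) -> None:
    """Write Y as TSV (samples x probes) plus a grid-describing sidecar JSON."""
    df = pd.DataFrame(cohort.Y, index=cohort.sample_ids,
                      columns=[f"vp{l}" for l in range(cohort.L)])
    df.to_csv(tsv_path, sep="\t", index_label="sample_id")
    with open(sidecar_json, "w") as fh:
        json.dump(cohort.grid.to_json(), fh, indent=1)


def read_cohort(tsv_path: str | Path, sidecar_json: str | Path) -> CohortMatrix:
    with open(sidecar_json) as fh:
        grid = VirtualGrid.from_json(json.load(fh))
    df = pd.read_csv(tsv_path, sep="\t", index_col="sample_id")
    return CohortMatrix(df.to_numpy(dtype=float), [str(s) for s in df.index], grid)
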