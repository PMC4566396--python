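"""Atom interpretation: probe calls -> cytoband alteration labels.

A fitted atom is a length-L vector on the virtual grid. Probes whose
magnitude clears a call threshold are flagged as gained (+1) or lost
(-1); a band is altered in a direction when at least one of its probes
is; maximal runs of adjacent same-direction bands are merged and
labelled in the conventional cytogenetic dialect:

* whole chromosome gained      -> "+7"
* whole arm                    -> "+17q"
* single sub-band              -> "+2p24.3"
* multi-band run               -> "+17q21-q22" (en dash in output)

Theta columns are binarized against a small threshold to produce the
per-sample atom patterns consumed by the tree-mixture stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .band_grid import CytobandMap, VirtualGrid

logger = logging.getLogger(__name__)

EN_DASH = "–"

DEFAULT_EPSILON = 0.1            # log2 call threshold
DEFAULT_THETA_THRESHOLD = 0.05   # fraction of theta_max


@dataclass(frozen=True)
class BandAlteration:
    """A maximal run of adjacent same-direction altered bands."""

    chrom: str
    first_band: int      # index into CytobandMap.bands
    last_band: int       # inclusive
    direction: int       # +1 gain, -1 loss

    def label(self, bands: CytobandMap) -> str:
        return format_label(self, bands)


def call_altered_probes(beta: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Signed per-probe call: +1 if beta_l >= eps, -1 if beta_l <= -eps, else 0."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    beta = np.asarray(beta, dtype=float)
    calls = np.zeros(beta.shape, dtype=int)
    calls[beta >= epsilon] = 1
    calls[beta <= -epsilon] = -1
    return calls


def _band_direction_votes(calls: np.ndarray, grid: VirtualGrid) -> dict[int, list[int]]:
    """Directions each band is altered in (majority rule; tie keeps both)."""
    out: dict[int, list[int]] = {}
    for bi in range(len(grid.bands)):
        c = calls[grid.probes_of_band(bi)]
        n_gain = int(np.sum(c == 1))
        n_loss = int(np.sum(c == -1))
        if n_gain == 0 and n_loss == 0:
            continue
        if n_gain > n_loss:
            out[bi] = [1]
        elif n_loss > n_gain:
            out[bi] = [-1]
        else:
            band = grid.bands.bands[bi]
            logger.info("band %s%s: tied gain/loss probe calls; reporting both",
                        band.chrom, band.name)
            out[bi] = [1, -1]
    return out


def probes_to_bands(calls: np.ndarray, grid: VirtualGrid) -> list[BandAlteration]:
    """Lift probe calls to merged band-level alterations.

    A band is altered in a direction when any of its probes is called in
    that direction (majority direction when a band mixes signs, both on
    a tie). Adjacent altered bands of the same direction on the same
    chromosome are merged into one alteration; runs may cross the
    centromere, which is how whole-chromosome labels arise.
    """
    calls = np.asarray(calls)
    if calls.shape != (grid.L,):
        raise ValueError("calls must align with the grid")
    votes = _band_direction_votes(calls, grid)
    alterations: list[BandAlteration] = []
    for direction in (1, -1):
        bis = sorted(bi for bi, dirs in votes.items() if direction in dirs)
        run_start = None
        prev = None
        for bi in bis + [None]:
            same_chrom = (
                bi is not None and prev is not None and bi == prev + 1
                and grid.bands.bands[bi].chrom == grid.bands.bands[prev].chrom
            )
            if run_start is not None and not same_chrom:
                alterations.append(BandAlteration(
                    chrom=grid.bands.bands[run_start].chrom,
                    first_band=run_start, last_band=prev, direction=direction))
                run_start = None
            if bi is not None and run_start is None:
                run_start = bi
            prev = bi
    alterations.sort(key=lambda a: (a.first_band, -a.direction))
    return alterations


def format_label(alt: BandAlteration, bands: CytobandMap) -> str:
    """Render a BandAlteration in the +/- cytogenetic label dialect."""
    sign = "+" if alt.direction > 0 else "-"
    chrom_band_idx = [i for i, b in enumerate(bands.bands) if b.chrom == alt.chrom]
    first, last = alt.first_band, alt.last_band
    b_first, b_last = bands.bands[first], bands.bands[last]
    if first == chrom_band_idx[0] and last == chrom_band_idx[-1]:
        arms = {bands.bands[i].arm for i in chrom_band_idx}
        if len(arms) > 1:
            return f"{sign}{alt.chrom}"           # both arms fully covered
        return f"{sign}{alt.chrom}{arms.pop()}"   # chromosome has one retained arm
    arm_idx = [i for i in chrom_band_idx if bands.bands[i].arm == b_first.arm]
    if b_first.arm == b_last.arm and first == arm_idx[0] and last == arm_idx[-1]:
        return f"{sign}{alt.chrom}{b_first.arm}"
    if first == last:
        return f"{sign}{alt.chrom}{b_first.name}"
    return f"{sign}{alt.chrom}{b_first.name}{EN_DASH}{b_last.name}"


def parse_label(label: str, bands: CytobandMap) -> BandAlteration:
    """Inverse of :func:`format_label` (used for round-trip validation)."""
    sign = label[0]
    if sign not in "+-":
        raise ValueError(f"label must start with + or -: {label!r}")
    direction = 1 if sign == "+" else -1
    body = label[1:]
    i = 0
    while i < len(body) and body[i].isdigit():
        i += 1
    chrom, rest = body[:i], body[i:]
    chrom_band_idx = [j for j, b in enumerate(bands.bands) if b.chrom == chrom]
    if not chrom_band_idx:
        raise ValueError(f"unknown chromosome in label {label!r}")
    if rest == "":
        return BandAlteration(chrom, chrom_band_idx[0], chrom_band_idx[-1], direction)
    if rest in ("p", "q"):
        arm_idx = [j for j in chrom_band_idx if bands.bands[j].arm == rest]
        return BandAlteration(chrom, arm_idx[0], arm_idx[-1], direction)
    if EN_DASH in rest:
        name0, name1 = rest.split(EN_DASH)
    else:
        name0 = name1 = rest
    by_name = {bands.bands[j].name: j for j in chrom_band_idx}
    try:
        return BandAlteration(chrom, by_name[name0], by_name[name1], direction)
    except KeyError as exc:
        raise ValueError(f"unknown band in label {label!r}") from exc


def binarize_theta(Theta: np.ndarray, threshold: float = DEFAULT_THETA_THRESHOLD) -> np.ndarray:
    """Indicator matrix of theta_js > threshold (same J x S shape as Theta).

    The threshold discards the smallest coefficients, which reflect
    solver inexactness rather than true atom usage; column s of the
    result is sample s's binary atom pattern.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (np.asarray(Theta) > threshold).astype(np.int8)


def atom_report(B: np.ndarray, grid: VirtualGrid, epsilon: float = DEFAULT_EPSILON,
                atom_ids: list[str] | None = None):
    """One row per atom: id, label list, structured alterations.

    Atoms with no altered band get an empty label list (they carry no
    interpretable alteration at the chosen threshold) and are flagged.
    """
    B = np.asarray(B, dtype=float)
    J = B.shape[1]
    if atom_ids is None:
        atom_ids = [f"A{j + 1}" for j in range(J)]
    rows = []
    for j in range(J):
        alts = probes_to_bands(call_altered_probes(B[:, j], epsilon), grid)
        rows.append({
            "atom": atom_ids[j],
            "labels": [a.label(grid.bands) for a in alts],
            "alterations": alts,
            "empty": len(alts) == 0,
        })
    return rows
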