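"""Synthetic cohorts with the structure the analysis assumes.

Generates every input the pipeline consumes, from planted ground truth:

* band-aligned piecewise-constant atoms (single-copy log2 magnitudes,
  +-0.5 by default, +-1 for two-copy events);
* sparse nonnegative coefficients in [0, 1] and probe-level Gaussian
  noise, giving a cohort Y = Theta* . B*^T + noise;
* probe-level profiles (jittered positions, per-band counts) that
  invert the K-NN alignment, for testing the grid stage;
* binary atom patterns drawn from a planted mixture of oncogenetic
  trees plus a star noise component;
* patient ages with an optional location shift for carriers of loss
  atoms, for the age-association stage.

Every generator is a pure function of its parameters and seed. The
default toy grid is 6 chromosomes x 5 bands x 10 probes (L = 300):
small enough for fast tests, large enough to exercise arm/centromere
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .band_grid import (Band, CohortMatrix, CytobandMap, ProbeProfile,
                        VirtualGrid, build_virtual_grid)
from .postprocess import parse_label
from .trees import OncogeneticTree, PatternSet, TreeMixture, ROOT

DEFAULT_BAND_WIDTH = 10_000_000


def toy_cytoband_map(n_chrom: int = 6, bands_per_arm: tuple[int, int] = (2, 3),
                     band_width: int = DEFAULT_BAND_WIDTH) -> CytobandMap:
    """A small autosome-only cytoband map with proper arms and centromeres.

    Each chromosome gets ``bands_per_arm`` (p, q) bands; the innermost
    p and q bands are acen-stained, so the centromere sits between them.
    """
    n_p, n_q = bands_per_arm
    bands: list[Band] = []
    centromeres: dict[str, int] = {}
    for ci in range(1, n_chrom + 1):
        chrom = str(ci)
        pos = 0
        p_names = [f"p{n_p - i}1" for i in range(n_p - 1)] + ["p11"]
        q_names = ["q11"] + [f"q{i + 1}1" for i in range(1, n_q)]
        for bi, name in enumerate(p_names + q_names):
            stain = "acen" if name in ("p11", "q11") else ("gneg" if bi % 2 else "gpos50")
            bands.append(Band(chrom, pos, pos + band_width, name, stain))
            if name == "p11":
                centromeres[chrom] = pos + band_width
            pos += band_width
    return CytobandMap(bands=bands, centromeres=centromeres)


def write_cytoband_file(bands: CytobandMap, path: str | Path) -> None:
    """Write a CytobandMap as a UCSC-format cytoBand.txt."""
    with open(path, "w") as fh:
        for b in bands.bands:
            fh.write(f"chr{b.chrom}\t{b.start}\t{b.end}\t{b.name}\t{b.stain}\n")


def default_toy_grid(n_per_band: int = 10) -> VirtualGrid:
    return build_virtual_grid(toy_cytoband_map(), n_per_band=n_per_band)


@dataclass
class PlantedModel:
    """Ground truth behind a synthetic cohort."""

    B: np.ndarray          # (L, J) band-aligned piecewise-constant atoms
    Theta: np.ndarray      # (J, S) sparse coefficients in [0, 1]
    noise_sd: float
    seed: int


# ---------------------------------------------------------------------------
# Atoms, cohorts, probe-level profiles
# ---------------------------------------------------------------------------

def generate_atoms(grid: VirtualGrid, J: int,
                   spec: list[list[tuple[str, float]]] | None = None,
                   seed: int = 0) -> np.ndarray:
    """Planted atom matrix B* (L x J), constant within every band.

    ``spec`` optionally fixes atoms: one list of events per atom, each
    event a (label, magnitude) pair where the label uses the alteration
    dialect ("+17q", "-3p", "+2p24.3") and magnitude > 0 scales the
    signed value. Atoms beyond the spec get 1-3 random whole-arm or
    sub-band events with magnitudes 0.5 or 1. Contradictory overlapping
    events within one atom raise.
    """
    rng = np.random.default_rng(seed)
    L = grid.L
    B = np.zeros((L, J))
    spec = list(spec or [])
    band_of = grid.band_of_probe()

    def apply_event(col: np.ndarray, label: str, magnitude: float) -> None:
        alt = parse_label(label, grid.bands)
        value = alt.direction * abs(magnitude)
        mask = (band_of >= alt.first_band) & (band_of <= alt.last_band)
        clash = mask & (col != 0) & (col != value)
        if np.any(clash):
            raise ValueError(f"event {label!r} contradicts an earlier event of this atom")
        col[mask] = value

    for j in range(J):
        col = B[:, j]
        if j < len(spec):
            for label, mag in spec[j]:
                apply_event(col, label, mag)
        else:
            n_events = rng.integers(1, 4)
            for _ in range(n_events):
                band = grid.bands.bands[rng.integers(0, len(grid.bands))]
                region = rng.choice([band.arm, band.name])
                sign = "+" if rng.random() < 0.5 else "-"
                mag = float(rng.choice([0.5, 1.0]))
                try:
                    apply_event(col, f"{sign}{band.chrom}{region}", mag)
                except ValueError:
                    pass  # skip a clashing random event, keep the atom valid
    return B


def generate_cohort(B_star: np.ndarray, S: int, grid: VirtualGrid,
                    sparsity: float = 2.0, noise_sd: float = 0.1,
                    seed: int = 0) -> tuple[CohortMatrix, np.ndarray]:
    """Cohort Y = Theta*^T B*^T + Gaussian probe noise; returns (cohort, Theta*).

    Each sample uses each atom independently with probability
    sparsity / J; used atoms get Uniform(0.5, 1) coefficients, so the
    expected number of active atoms per sample is ``sparsity``.
    """
    B_star = np.asarray(B_star, dtype=float)
    L, J = B_star.shape
    if L != grid.L:
        raise ValueError("B* rows must match the grid length")
    if not 0 <= sparsity <= J:
        raise ValueError("sparsity must lie in [0, J]")
    rng = np.random.default_rng(seed)
    support = rng.random((J, S)) < sparsity / J
    Theta = np.where(support, rng.uniform(0.5, 1.0, size=(J, S)), 0.0)
    Y = (B_star @ Theta).T + rng.normal(0.0, noise_sd, size=(S, L))
    ids = [f"S{s + 1}" for s in range(S)]
    return CohortMatrix(Y, ids, grid), Theta


def _band_counts(rng: np.random.Generator, n_bands: int, probes_per_band) -> np.ndarray:
    if isinstance(probes_per_band, int):
        return np.full(n_bands, probes_per_band)
    if isinstance(probes_per_band, tuple) and len(probes_per_band) == 2:
        lo, hi = probes_per_band
        return rng.integers(lo, hi + 1, size=n_bands)
    counts = np.asarray(probes_per_band, dtype=int)
    if counts.shape != (n_bands,):
        raise ValueError("per-band counts must have one entry per band")
    return counts


def generate_probe_level(cohort: CohortMatrix, grid: VirtualGrid,
                         probes_per_band=10, noise_sd: float = 0.0,
                         seed: int = 0) -> list[ProbeProfile]:
    """Invert the alignment: scatter real probes inside each band.

    Each band receives ``probes_per_band`` probes (an int, a (lo, hi)
    range, or per-band counts; 0 exercises the empty-band imputation
    path) at uniformly jittered positions; each probe's value is the
    band's mean cohort value plus independent Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    n_bands = len(grid.bands)
    for si, sid in enumerate(cohort.sample_ids):
        counts = _band_counts(rng, n_bands, probes_per_band)
        chroms, positions, values, ids = [], [], [], []
        for bi, band in enumerate(grid.bands.bands):
            m = int(counts[bi])
            if m == 0:
                continue
            band_value = float(cohort.Y[si, grid.probes_of_band(bi)].mean())
            pos = np.sort(rng.integers(band.start, band.end, size=m))
            val = band_value + rng.normal(0.0, noise_sd, size=m)
            for p, v in zip(pos, val):
                ids.append(f"{sid}_b{bi}_{p}")
                chroms.append(band.chrom)
                positions.append(int(p))
                values.append(float(v))
        profiles.append(ProbeProfile(
            sample_id=sid, probe_ids=ids, chrom=np.array(chroms, dtype=object),
            position=np.array(positions, dtype=int), log2=np.array(values)))
    return profiles


# ---------------------------------------------------------------------------
# Patterns, mixtures, ages
# ---------------------------------------------------------------------------

def make_planted_mixture(topologies: list[tuple[np.ndarray, np.ndarray]],
                         weights: np.ndarray,
                         star_marginals: np.ndarray) -> TreeMixture:
    """Assemble a TreeMixture from (parent, prob) pairs plus a star component.

    ``weights`` orders as (star, tree_1, ..., tree_K) and must sum to 1.
    """
    J = len(star_marginals)
    star = OncogeneticTree(parent=np.full(J, ROOT),
                           prob=np.clip(star_marginals, 1e-12, 1 - 1e-12))
    trees = [star] + [
        OncogeneticTree(np.asarray(p), np.clip(np.asarray(q, dtype=float),
                                               1e-12, 1 - 1e-12))
        for p, q in topologies
    ]
    return TreeMixture(trees=trees, weights=np.asarray(weights, dtype=float))


def default_planted_mixture(J: int = 6) -> TreeMixture:
    """The benchmark mixture: two progression pathways plus 10% noise.

    The two trees wire the same J atoms as chains in opposite order
    (distinct initiating lesions), so their pattern supports barely
    overlap and the mixture is identifiable at moderate sample sizes.
    Edge probabilities follow typical reported alteration frequencies:
    ~0.7-0.8 for initiating events, 0.5-0.6 deeper in the chain. The
    star noise component has weight 0.1 and marginal rate 0.2 per atom.
    """
    if J != 6:
        raise ValueError("the default planted mixture is defined for J = 6")
    t1 = (np.array([-1, 0, 1, -1, 3, 4]), np.array([.8, .6, .5, .7, .6, .5]))
    t2 = (np.array([1, 2, -1, 4, 5, -1]), np.array([.5, .6, .8, .5, .6, .7]))
    return make_planted_mixture([t1, t2], np.array([0.1, 0.45, 0.45]),
                                np.full(J, 0.2))


def _topological_order(parent: np.ndarray) -> list[int]:
    order, placed = [], set()
    remaining = list(range(parent.size))
    while remaining:
        progressed = False
        for v in list(remaining):
            u = int(parent[v])
            if u == ROOT or u in placed:
                order.append(v)
                placed.add(v)
                remaining.remove(v)
                progressed = True
        if not progressed:
            raise ValueError("parent map contains a cycle")
    return order


def sample_patterns(mix: TreeMixture, n: int, seed: int = 0) -> PatternSet:
    """Draw n patterns: pick a component by weight, then sample root-down.

    Within the chosen tree, each atom is present with its edge
    probability only if its parent is present (root children always
    eligible) — the generative counterpart of the pattern likelihood.
    """
    rng = np.random.default_rng(seed)
    J = mix.trees[0].J
    X = np.zeros((n, J), dtype=np.int8)
    comp = rng.choice(len(mix.trees), size=n, p=mix.weights / mix.weights.sum())
    orders = [_topological_order(T.parent) for T in mix.trees]
    for i in range(n):
        T = mix.trees[comp[i]]
        for v in orders[comp[i]]:
            u = int(T.parent[v])
            if u == ROOT or X[i, u] == 1:
                X[i, v] = rng.random() < T.prob[v]
    return PatternSet(X)


def generate_ages(patterns, loss_atoms, effect: float = 0.0, seed: int = 0,
                  base_median: float = 18.0, base_sigma: float = 0.6) -> np.ndarray:
    """Ages in months: LogNormal baseline plus a shift for loss-atom carriers.

    A sample is a carrier when it holds at least one atom of
    ``loss_atoms``; carriers' ages are shifted up by ``effect`` months,
    emulating the accumulation of chromosome losses with patient age.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    X = patterns.X if isinstance(patterns, PatternSet) else np.asarray(patterns)
    rng = np.random.default_rng(seed)
    ages = rng.lognormal(np.log(base_median), base_sigma, size=X.shape[0])
    carrier = X[:, list(loss_atoms)].any(axis=1) if len(list(loss_atoms)) else np.zeros(X.shape[0], bool)
    return ages + effect * carrier


# ---------------------------------------------------------------------------
# File writers for end-to-end runs
# ---------------------------------------------------------------------------

def write_probe_level_inputs(profiles: list[ProbeProfile], probe_map_tsv: str | Path,
                             logratio_tsv: str | Path) -> None:
    """Write a shared probe map and a probes x samples log-ratio matrix.

    All profiles must share the same probe layout (as produced by
    :func:`generate_probe_level` with a fixed seed-driven layout per
    sample is NOT shared; this writer requires identical probe ids).
    """
    ref = profiles[0]
    for p in profiles[1:]:
        if len(p.probe_ids) != len(ref.probe_ids):
            raise ValueError("profiles must share one probe layout to share a probe map")
    pmap = pd.DataFrame({"probe_id": ref.probe_ids, "chrom": ref.chrom,
                         "pos": ref.position})
    pmap.to_csv(probe_map_tsv, sep="\t", index=False)
    mat = pd.DataFrame({p.sample_id: p.log2 for p in profiles}, index=ref.probe_ids)
    mat.to_csv(logratio_tsv, sep="\t", index_label="probe_id")


def shared_layout_probe_level(cohort: CohortMatrix, grid: VirtualGrid,
                              probes_per_band=10, noise_sd: float = 0.0,
                              seed: int = 0) -> list[ProbeProfile]:
    """Probe-level profiles with one probe layout shared by all samples,
    suitable for the probe-map + matrix file format."""
    rng = np.random.default_rng(seed)
    n_bands = len(grid.bands)
    counts = _band_counts(rng, n_bands, probes_per_band)
    chroms, positions, ids, band_idx = [], [], [], []
    for bi, band in enumerate(grid.bands.bands):
        pos = np.sort(rng.integers(band.start, band.end, size=int(counts[bi])))
        for p in pos:
            ids.append(f"p_b{bi}_{p}")
            chroms.append(band.chrom)
            positions.append(int(p))
            band_idx.append(bi)
    chroms = np.array(chroms, dtype=object)
    positions = np.array(positions, dtype=int)
    profiles = []
    for si, sid in enumerate(cohort.sample_ids):
        vals = np.array([
            float(cohort.Y[si, grid.probes_of_band(bi)].mean()) for bi in band_idx
        ]) + rng.normal(0.0, noise_sd, size=len(band_idx))
        profiles.append(ProbeProfile(sample_id=sid, probe_ids=list(ids),
                                     chrom=chroms, position=positions, log2=vals))
    return profiles


def write_manifest(sample_ids: list[str], stages: list[str], ages: np.ndarray | None,
                   path: str | Path, platform: str = "synthetic") -> None:
    df = pd.DataFrame({"sample_id": sample_ids, "stage": stages,
                       "age": ages if ages is not None else np.nan,
                       "platform": platform})
    df.to_csv(path, index=False)
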