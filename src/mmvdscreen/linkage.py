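"""Pairwise linkage disequilibrium (r^2) and perfect-LD haplotype collapse.

Two estimators are provided. The composite estimator is the squared
Pearson correlation of allele dosages over pairwise-complete samples: it
is phase-free, deterministic, and equals the haplotype-based r^2 whenever
gametic phase is unambiguous — in particular in the perfect-LD case the
screening pipeline relies on. The EM estimator recovers maximum-likelihood
haplotype frequencies from the 3x3 genotype table (the double heterozygote
being the only phase-ambiguous class) and computes r^2 = D^2 / (pA qA pB qB).
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx
import numpy as np

from .model import MISSING, GenotypeCohort, HaplotypeGroup, LDPair, ValidationError

log = logging.getLogger(__name__)


def _pairwise_complete(dosage_a: np.ndarray, dosage_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(dosage_a)
    b = np.asarray(dosage_b)
    if a.shape != b.shape:
        raise ValidationError("dosage vectors differ in length")
    mask = (a != MISSING) & (b != MISSING)
    return a[mask].astype(float), b[mask].astype(float)


def _em_r2(a: np.ndarray, b: np.ndarray, max_iter: int = 200, tol: float = 1e-12) -> float:
    """r^2 from EM maximum-likelihood haplotype frequencies.

    Haplotypes are indexed by (allele at A, allele at B) in {0,1}^2. All
    genotype classes except the double heterozygote phase unambiguously;
    the EM step splits the double-het mass between cis (0,0)/(1,1) and
    trans (0,1)/(1,0) resolutions in proportion to current frequencies.
    """
    n = len(a)
    table = np.zeros((3, 3))
    for ga, gb in zip(a.astype(int), b.astype(int)):
        table[ga, gb] += 1
    n_dh = table[1, 1]
    # Unambiguous haplotype counts: genotype g contributes g copies of
    # allele 1 and (2-g) of allele 0 at each locus, phased except for 1/1.
    counts = np.zeros((2, 2))
    for ga in range(3):
        for gb in range(3):
            if ga == 1 and gb == 1:
                continue
            c = table[ga, gb]
            if c == 0:
                continue
            ha = [0] * (2 - ga) + [1] * ga
            hb = [0] * (2 - gb) + [1] * gb
            if ga == 1:
                counts[0, hb[0]] += c
                counts[1, hb[1]] += c
            elif gb == 1:
                counts[ha[0], 0] += c
                counts[ha[1], 1] += c
            else:
                counts[ha[0], hb[0]] += 2 * c
    freq = np.full((2, 2), 0.25)
    for _ in range(max_iter):
        cis = freq[0, 0] * freq[1, 1]
        trans = freq[0, 1] * freq[1, 0]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        new = counts.copy()
        new[0, 0] += n_dh * w
        new[1, 1] += n_dh * w
        new[0, 1] += n_dh * (1 - w)
        new[1, 0] += n_dh * (1 - w)
        new /= 2 * n
        if np.max(np.abs(new - freq)) < tol:
            freq = new
            break
        freq = new
    p_a = freq[1, 0] + freq[1, 1]
    p_b = freq[0, 1] + freq[1, 1]
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        raise ValidationError("LD undefined: monomorphic locus after EM")
    d = freq[1, 1] - p_a * p_b
    return float(min(d * d / denom, 1.0))


def genotype_r2(
    dosage_a: np.ndarray,
    dosage_b: np.ndarray,
    method: str = "composite",
    marker_a: str = "A",
    marker_b: str = "B",
) -> LDPair:
    """Pairwise r^2 between two markers' dosage vectors.

    Missing data are handled by pairwise deletion; ``n_pairs`` records the
    jointly-called sample count. A locus monomorphic among the jointly
    called samples makes LD undefined and raises ``ValidationError``
    (never silently r^2 = 0).
    """
    a, b = _pairwise_complete(dosage_a, dosage_b)
    if len(a) < 2:
        raise ValidationError(
            f"LD between {marker_a} and {marker_b}: fewer than 2 jointly called samples"
        )
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError(
            f"LD undefined: monomorphic locus among jointly called samples "
            f"({marker_a} vs {marker_b})"
        )
    if method == "composite":
        r = np.corrcoef(a, b)[0, 1]
        r2 = float(min(r * r, 1.0))
        if 1.0 - r2 < 1e-12:  # identical-vector case up to float jitter
            r2 = 1.0
    elif method == "em_haplotype":
        r2 = _em_r2(a, b)
    else:
        raise ValueError(f"unknown LD method {method!r}")
    return LDPair(marker_a=marker_a, marker_b=marker_b, r2=r2, n_pairs=len(a))


def ld_profile(
    cohort: GenotypeCohort,
    target_marker: str,
    window: tuple[str, int, int],
    method: str = "composite",
) -> list[LDPair]:
    """r^2 of every polymorphic marker in a window against a target marker.

    Monomorphic markers are skipped with a log entry; results are sorted by
    marker position. The target itself is excluded.
    """
    chrom, start, end = window
    target = cohort.marker(target_marker)
    if not (target.chrom == chrom and start <= target.pos <= end):
        raise ValidationError(f"target {target_marker} lies outside window {window}")
    d_t = cohort.dosage_vector(target_marker)
    if np.ptp(d_t[d_t != MISSING]) == 0:
        raise ValidationError(f"target marker {target_marker} is monomorphic")
    pairs = []
    for m in cohort.markers:
        if m.marker_id == target_marker or m.chrom != chrom or not start <= m.pos <= end:
            continue
        try:
            pairs.append(
                genotype_r2(
                    d_t,
                    cohort.dosage_vector(m.marker_id),
                    method=method,
                    marker_a=target_marker,
                    marker_b=m.marker_id,
                )
            )
        except ValidationError:
            log.info("marker %s monomorphic or uncallable; skipped from LD profile", m.marker_id)
    pos = {m.marker_id: m.pos for m in cohort.markers}
    pairs.sort(key=lambda p: pos[p.marker_b])
    return pairs


def collapse_perfect_ld(
    pairs: list[LDPair],
    tolerance: float = 1e-9,
    positions: dict[str, int] | None = None,
) -> list[HaplotypeGroup]:
    """Group markers connected by (near-)perfect LD into haplotype groups.

    Groups are connected components of the graph whose edges join marker
    pairs with r^2 >= 1 - tolerance; markers mentioned only in sub-perfect
    pairs become singletons. The representative is the lowest-position
    member when ``positions`` is given, else the lexicographically first.
    """
    g = nx.Graph()
    for p in pairs:
        g.add_node(p.marker_a)
        g.add_node(p.marker_b)
        if p.r2 >= 1.0 - tolerance:
            g.add_edge(p.marker_a, p.marker_b)
    key = (lambda m: positions[m]) if positions else (lambda m: m)
    groups = []
    for i, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: min(key(m) for m in c))):
        members = set(comp)
        groups.append(
            HaplotypeGroup(
                group_id=f"hap{i + 1}",
                member_markers=members,
                representative=min(members, key=key),
            )
        )
    return groups
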