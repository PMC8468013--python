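"""Primer-pair design inside a marker gene and in-silico PCR validation.

Primer-level melting temperature uses the Wallace rule, Tm = 2·(A+T) +
4·(G+C), adequate for the 18–24-mers designed here.  Amplicon Tm uses the
salt-adjusted empirical formula Tm = 81.5 + 0.41·GC% − 675/N +
16.6·log10[Na+].  Product length follows the synthesis convention: the
inclusive span between the two primers' outermost 5' ends, so two 20-mers
with an 88 nt insert give a 128 bp product.

In-silico PCR scans every sequence (both strands) for primer binding sites
within a mismatch tolerance, requiring the 3'-terminal 3 nt to match
exactly (polymerase extension is launched from the 3' end), and reports
every inward-facing opposite-strand site pair within the product cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .clustering import project_onto_rep
from .genome_io import GenomeSet, compute_gc, reverse_complement


@dataclass
class PrimerConstraints:
    primer_len: tuple[int, int] = (18, 24)
    gc_range: tuple[float, float] = (0.40, 0.60)
    tm_range: tuple[float, float] = (55.0, 65.0)
    max_homopolymer: int = 4          # reject runs of ≥ max_homopolymer+1
    product_range: tuple[int, int] = (80, 200)
    product_optimum: int = 130
    max_tm_diff: float = 3.0

    def __post_init__(self) -> None:
        if self.gc_range[0] > self.gc_range[1]:
            raise ValueError("empty GC interval")
        if self.primer_len[0] > self.primer_len[1]:
            raise ValueError("empty primer-length interval")
        if self.product_range[0] > self.product_range[1]:
            raise ValueError("empty product-size interval")


@dataclass(frozen=True)
class PrimerPair:
    """forward_seq / reverse_seq are both written 5'→3' as synthesized;
    the reverse primer is the reverse complement of the template plus
    strand.  Coordinates are 0-based half-open on the marker."""

    forward_seq: str
    reverse_seq: str
    forward_start: int
    reverse_end: int  # template position just past the reverse binding site

    @property
    def product_size(self) -> int:
        return self.reverse_end - self.forward_start

    @property
    def forward_tm(self) -> float:
        return wallace_tm(self.forward_seq)

    @property
    def reverse_tm(self) -> float:
        return wallace_tm(self.reverse_seq)

    @property
    def forward_gc(self) -> float:
        return compute_gc(self.forward_seq)

    @property
    def reverse_gc(self) -> float:
        return compute_gc(self.reverse_seq)


@dataclass(frozen=True)
class SiteHit:
    start: int
    end: int
    strand: str  # '+' site read on plus strand, '-' site on minus strand
    mismatches: int


@dataclass
class AmpliconHit:
    genome_id: str
    gene_id: str
    forward_site: SiteHit
    reverse_site: SiteHit
    product_length: int
    product_gc: float
    product_tm: Optional[float]


@dataclass
class SpecificityReport:
    hits: list[AmpliconHit]
    amplified: dict[str, bool]          # genome_id → verdict
    target_genome_ids: list[str]
    nontarget_genome_ids: list[str]

    @property
    def n_target_amplified(self) -> int:
        return sum(self.amplified[g] for g in self.target_genome_ids)

    @property
    def n_nontarget_amplified(self) -> int:
        return sum(self.amplified[g] for g in self.nontarget_genome_ids)

    @property
    def specific(self) -> bool:
        return (self.n_target_amplified == len(self.target_genome_ids)
                and self.n_nontarget_amplified == 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"genome_id": g,
                 "role": ("target" if g in self.target_genome_ids
                          else "non-target"),
                 "amplified": self.amplified[g],
                 "n_amplicons": sum(h.genome_id == g for h in self.hits)}
                for g in self.target_genome_ids + self.nontarget_genome_ids]
        return pd.DataFrame(rows)


def wallace_tm(primer_seq: str) -> float:
    """Wallace rule Tm = 2(A+T) + 4(G+C), °C; valid for ≤30-mers."""
    if len(primer_seq) > 30:
        raise ValueError("Wallace rule is only meaningful for ≤30-mers")
    s = primer_seq.upper()
    return 2.0 * (s.count("A") + s.count("T")) + 4.0 * (s.count("G") + s.count("C"))


def product_tm(product_seq: str, na_molar: float = 0.05) -> float:
    """Salt-adjusted empirical duplex Tm, reported to the nearest 0.5 °C."""
    n = len(product_seq)
    if n < 50:
        raise ValueError("product Tm formula invalid below 50 bp")
    gc_pct = 100.0 * compute_gc(product_seq)
    tm = 81.5 + 0.41 * gc_pct - 675.0 / n + 16.6 * math.log10(na_molar)
    return round(tm * 2.0) / 2.0


def _homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _primer_ok(seq: str, c: PrimerConstraints) -> bool:
    if "N" in seq:
        return False
    if not c.gc_range[0] <= compute_gc(seq) <= c.gc_range[1]:
        return False
    if not c.tm_range[0] <= wallace_tm(seq) <= c.tm_range[1]:
        return False
    if _homopolymer_run(seq) > c.max_homopolymer:
        return False
    return True


def conservation_mask(rep_seq: str, member_seqs: list[str]) -> np.ndarray:
    """Per-position flag: is the representative base identical in every
    member copy of the gene?  Members are projected onto representative
    coordinates; a gap counts as non-conserved.  Primer windows restricted
    to conserved positions bind every strain of the clade exactly."""
    mask = np.ones(len(rep_seq), dtype=bool)
    rep_arr = np.frombuffer(rep_seq.encode(), dtype=np.uint8)
    for member in member_seqs:
        proj = project_onto_rep(rep_seq, member)
        mask &= np.frombuffer(proj.encode(), dtype=np.uint8) == rep_arr
    return mask


def design_primers(marker_seq: str,
                   constraints: PrimerConstraints | None = None,
                   max_pairs: int = 50,
                   conserved_mask: Optional[np.ndarray] = None) -> list[PrimerPair]:
    """Enumerate and rank all compliant primer pairs on a marker sequence.

    When ``conserved_mask`` is given (see :func:`conservation_mask`),
    primer windows are restricted to fully conserved positions so the pair
    amplifies every strain of the target clade.  Ranking is deterministic:
    |ΔTm| first, then closeness of product size to the optimum, then a soft
    preference for G/C 3' ends, then leftmost coordinates.  Raises with the
    binding constraint when nothing passes.
    """
    c = constraints or PrimerConstraints()
    marker = marker_seq.upper()
    lmin, lmax = c.primer_len
    if len(marker) < c.product_range[0]:
        raise ValueError(
            f"marker ({len(marker)} nt) shorter than the minimum product "
            f"size {c.product_range[0]}"
        )
    if conserved_mask is not None and len(conserved_mask) != len(marker):
        raise ValueError("conserved_mask length must equal marker length")

    # forward windows: primer equals the template slice
    fwd: list[tuple[int, int]] = []   # (start, length)
    rev: list[tuple[int, int]] = []   # reverse windows keyed by (end, length)
    for length in range(lmin, lmax + 1):
        for start in range(0, len(marker) - length + 1):
            if (conserved_mask is not None
                    and not conserved_mask[start:start + length].all()):
                continue
            window = marker[start:start + length]
            if _primer_ok(window, c):
                fwd.append((start, length))
            if _primer_ok(reverse_complement(window), c):
                rev.append((start + length, length))
    if not fwd or not rev:
        which = "forward" if not fwd else "reverse"
        raise ValueError(
            f"no {which} primer window satisfies the primer-level "
            f"constraints (length {c.primer_len}, GC {c.gc_range}, "
            f"Tm {c.tm_range}, homopolymer ≤ {c.max_homopolymer})"
        )

    rev_by_end: dict[int, list[tuple[int, int]]] = {}
    for end, length in rev:
        rev_by_end.setdefault(end, []).append((end, length))

    pairs: list[tuple[tuple, PrimerPair]] = []
    for fstart, flen in fwd:
        f_seq = marker[fstart:fstart + flen]
        f_tm = wallace_tm(f_seq)
        for product in range(c.product_range[0], c.product_range[1] + 1):
            rend = fstart + product
            if rend > len(marker):
                break
            for _, rlen in rev_by_end.get(rend, ()):
                if rend - rlen < fstart + flen:
                    continue  # primers must not overlap
                r_seq = reverse_complement(marker[rend - rlen:rend])
                dtm = abs(f_tm - wallace_tm(r_seq))
                if dtm > c.max_tm_diff:
                    continue
                soft = (f_seq[-1] not in "GC") + (r_seq[-1] not in "GC")
                key = (dtm, abs(product - c.product_optimum), soft,
                       fstart, rend, flen, rlen)
                pairs.append((key, PrimerPair(
                    forward_seq=f_seq, reverse_seq=r_seq,
                    forward_start=fstart, reverse_end=rend)))
    if not pairs:
        raise ValueError(
            "primer windows exist but no pair satisfies the pairing "
            f"constraints (product {c.product_range}, "
            f"|ΔTm| ≤ {c.max_tm_diff} °C)"
        )
    pairs.sort(key=lambda kv: kv[0])
    return [p for _, p in pairs[:max_pairs]]


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _find_sites(template: np.ndarray, primer: str, tolerance: int,
                clamp: int = 3) -> list[tuple[int, int]]:
    """Positions (start, mismatches) where primer matches the template
    left-to-right within tolerance, 3'-terminal ``clamp`` nt exact.
    N in the template never matches."""
    p = _encode(primer)
    L = len(p)
    if len(template) < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(template, L)
    mism = (windows != p).sum(axis=1)
    clamp_ok = (windows[:, L - clamp:] == p[L - clamp:]).all(axis=1)
    idx = np.nonzero((mism <= tolerance) & clamp_ok)[0]
    return [(int(i), int(mism[i])) for i in idx]


def _scan_sequence(seq: str, pair: PrimerPair, tolerance: int,
                   max_product: int) -> list[tuple[SiteHit, SiteHit, int]]:
    """All inward-facing opposite-strand site pairs on one template."""
    t = _encode(seq.upper())
    n = len(t)
    fwd, rvs = pair.forward_seq, pair.reverse_seq
    lf, lr = len(fwd), len(rvs)

    def plus(primer):  # primer lies along the plus strand
        return _find_sites(t, primer, tolerance)

    def minus(primer):
        # primer binds the minus strand: its reverse complement appears on
        # the plus strand; the primer 3' end maps to the site start, so the
        # exact-clamp region is the *first* bases of the plus-strand motif.
        rc = reverse_complement(primer)
        p = _encode(rc)
        L = len(p)
        if n < L:
            return []
        windows = np.lib.stride_tricks.sliding_window_view(t, L)
        mism = (windows != p).sum(axis=1)
        clamp_ok = (windows[:, :3] == p[:3]).all(axis=1)
        idx = np.nonzero((mism <= tolerance) & clamp_ok)[0]
        return [(int(i), int(mism[i])) for i in idx]

    out = []
    # orientation 1: forward on plus, reverse on minus
    f_sites = plus(fwd)
    r_sites = minus(rvs)
    for fs, fm in f_sites:
        for rs, rm in r_sites:
            span = rs + lr - fs
            if max(lf, lr) <= span <= max_product and fs + lf <= rs + lr:
                out.append((SiteHit(fs, fs + lf, "+", fm),
                            SiteHit(rs, rs + lr, "-", rm), span))
    # orientation 2: reverse on plus, forward on minus (flipped template)
    r_plus = plus(rvs)
    f_minus = minus(fwd)
    for rs, rm in r_plus:
        for fs, fm in f_minus:
            span = fs + lf - rs
            if max(lf, lr) <= span <= max_product and rs + lr <= fs + lf:
                out.append((SiteHit(fs, fs + lf, "-", fm),
                            SiteHit(rs, rs + lr, "+", rm), span))
    return out


def insilico_pcr(pair: PrimerPair, genome_set: GenomeSet,
                 tolerance: int = 2, max_product: int = 3000) -> SpecificityReport:
    """Predict amplification of a primer pair across the whole genome set.

    A genome is "amplified" when at least one of its sequences carries an
    inward-facing opposite-strand site pair within tolerance (3'-clamp
    exact) producing ≤ ``max_product`` bp.
    """
    hits: list[AmpliconHit] = []
    amplified: dict[str, bool] = {}
    for genome in genome_set.genomes:
        got = False
        for gene in genome.genes:
            for fsite, rsite, span in _scan_sequence(gene.seq, pair,
                                                     tolerance, max_product):
                left = min(fsite.start, rsite.start)
                product = gene.seq[left:left + span]
                hits.append(AmpliconHit(
                    genome_id=genome.genome_id, gene_id=gene.gene_id,
                    forward_site=fsite, reverse_site=rsite,
                    product_length=span,
                    product_gc=compute_gc(product),
                    product_tm=(product_tm(product) if span >= 50 else None),
                ))
                got = True
        amplified[genome.genome_id] = got
    return SpecificityReport(
        hits=hits, amplified=amplified,
        target_genome_ids=[g.genome_id for g in genome_set.target_genomes],
        nontarget_genome_ids=[g.genome_id for g in genome_set.nontarget_genomes],
    )


def primer_table(pairs: list[PrimerPair], species: str = "") -> pd.DataFrame:
    rows = []
    for i, p in enumerate(pairs, 1):
        rows.append({"species": species, "primer_name": f"pair{i}-F",
                     "sequence_5to3": p.forward_seq,
                     "product_size_bp": p.product_size})
        rows.append({"species": species, "primer_name": f"pair{i}-R",
                     "sequence_5to3": p.reverse_seq,
                     "product_size_bp": p.product_size})
    return pd.DataFrame(rows)
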