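"""Multipoint conditional probabilities of QTL genotypes and their
correction by fitted SDL fitnesses.

An F2 individual carries one female- and one male-derived chromosome.
Along a chromosome the ordered genotype at each locus is one of four
states (female allele, male allele): AA, Aa, aA, aa.  The two strands
recombine independently, so the transition matrix between adjacent loci
is the Kronecker product of two 2-state chains with the same
recombination fraction (obtained from the map distance with the Kosambi
function; no interference is modelled beyond the map-function
conversion).  Marker observations restrict the compatible ordered states
(codominant codes pin the unordered genotype, dominant codes exclude one
homozygote, missing excludes nothing); forward-backward then yields the
posterior distribution of ordered states at any scan position.

No selection enters this computation: distortion is corrected post hoc by
reweighting the three genotype classes with the relative fitnesses
implied by a fitted SDL pair (see :func:`correct_conditional_probs`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_map import ChromosomeMap, GenotypeMatrix, LinkageMap, r_from_d

__all__ = [
    "ScanGrid",
    "ConditionalProbMatrix",
    "ExpectedDummies",
    "MultipointEngine",
    "multipoint_qtl_probs",
    "insert_virtual_markers",
    "position_fitness",
    "correct_conditional_probs",
    "expected_dummies",
]

# emission masks over ordered states (AA, Aa, aA, aa) for the six codes
_EMISSION = np.array(
    [
        [1, 0, 0, 0],  # AA
        [0, 1, 1, 0],  # Aa (unordered heterozygote)
        [0, 0, 0, 1],  # aa
        [1, 1, 1, 0],  # A- : not aa
        [0, 1, 1, 1],  # a- : not AA
        [1, 1, 1, 1],  # missing
    ],
    dtype=float,
)

_PRIOR4 = np.array([0.25, 0.25, 0.25, 0.25])

# collapse ordered states to (QQ, Qq, qq)
_COLLAPSE = np.array(
    [
        [1, 0, 0],
        [0, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
    ],
    dtype=float,
)


class DegenerateCorrectionError(ValueError):
    """Fitness correction annihilated an individual's probability row."""


@dataclass
class ScanGrid:
    """Scan positions per chromosome, with inserted virtual markers flagged."""

    chromosomes: list[str]
    positions: dict[str, np.ndarray]
    is_virtual: dict[str, np.ndarray]

    def n_positions(self) -> int:
        return sum(len(p) for p in self.positions.values())


@dataclass
class ConditionalProbMatrix:
    """Posterior QTL-genotype probabilities per individual and position.

    ``probs4`` holds the four ordered classes (AA, Aa, aA, aa) internally;
    ``probs3`` collapses the two heterozygote orders.
    Shape: (n_individuals, n_positions, 4).
    """

    chrom: str
    positions: np.ndarray
    probs4: np.ndarray

    @property
    def probs3(self) -> np.ndarray:
        return self.probs4 @ _COLLAPSE

    @property
    def n_individuals(self) -> int:
        return self.probs4.shape[0]

    def at_position(self, pos: float) -> np.ndarray:
        """(n, 3) probabilities at one scan position."""
        k = int(np.argmin(np.abs(self.positions - pos)))
        if abs(self.positions[k] - pos) > 1e-6:
            raise KeyError(f"position {pos} not on the scan grid of {self.chrom!r}")
        return self.probs3[:, k, :]


@dataclass
class ExpectedDummies:
    """Expected additive (z) and dominance (w) regressors per individual
    and putative QTL position: E[z] = p(QQ) - p(qq), E[w] = p(Qq)."""

    chrom: str
    positions: np.ndarray
    z: np.ndarray  # (n, n_positions)
    w: np.ndarray


# ---------------------------------------------------------------------------
# forward-backward engine


class MultipointEngine:
    """Forward-backward over the 4 ordered one-locus states along one
    chromosome, for all individuals at once.

    Parameters
    ----------
    chrom : ChromosomeMap
    genotypes : GenotypeMatrix
        Must contain every marker of ``chrom``; other markers are ignored.
    extra_positions : array_like, optional
        Non-marker positions (virtual markers / scan queries), treated as
        fully missing observations.
    map_function : str
        ``"kosambi"`` (default) or ``"haldane"``.
    """

    def __init__(self, chrom: ChromosomeMap, genotypes: GenotypeMatrix,
                 extra_positions=None, map_function: str = "kosambi"):
        self.chrom = chrom
        n = genotypes.n_individuals
        marker_pos = np.asarray(chrom.positions, dtype=float)
        lo, hi = marker_pos[0], marker_pos[-1]
        extra = np.atleast_1d(np.asarray(extra_positions if extra_positions
                                         is not None else [], dtype=float))
        if extra.size and (extra.min() < lo - 1e-9 or extra.max() > hi + 1e-9):
            raise ValueError(
                f"scan position outside chromosome {chrom.name!r} span "
                f"[{lo}, {hi}] cM"
            )
        # merge marker and extra positions; drop extras that coincide with a
        # marker or an already-added extra
        positions = list(marker_pos)
        sources = list(range(len(marker_pos)))  # marker column index or -1
        added: list[float] = []
        for p in extra:
            if np.min(np.abs(marker_pos - p)) <= 1e-9:
                continue
            if added and min(abs(p - q) for q in added) <= 1e-9:
                continue
            positions.append(p)
            sources.append(-1)
            added.append(p)
        order = np.argsort(positions, kind="stable")
        self.positions = np.asarray(positions)[order]
        self.sources = np.asarray(sources)[order]

        L = len(self.positions)
        obs = np.full((n, L), 5, dtype=np.int8)
        cols = {m: genotypes.markers.index(m) for m in chrom.markers}
        for k, src in enumerate(self.sources):
            if src >= 0:
                obs[:, k] = genotypes.codes[:, cols[chrom.markers[src]]]
        self.emissions = _EMISSION[obs]          # (n, L, 4)
        self.individuals = genotypes.individuals

        d = np.diff(self.positions)
        r = np.asarray([r_from_d(di, map_function) for di in d])
        strand = np.stack([np.stack([1 - r, r], -1),
                           np.stack([r, 1 - r], -1)], -2)  # (L-1, 2, 2)
        self.transitions = np.einsum("kab,kcd->kacbd", strand, strand)
        self.transitions = self.transitions.reshape(len(d), 4, 4)
        self._alpha = None
        self._beta = None

    def locus_index(self, pos: float) -> int:
        k = int(np.argmin(np.abs(self.positions - pos)))
        if abs(self.positions[k] - pos) > 1e-6:
            raise KeyError(f"position {pos} not among engine loci")
        return k

    def _run(self):
        if self._alpha is not None:
            return
        e = self.emissions
        n, L, _ = e.shape
        alpha = np.empty((n, L, 4))
        beta = np.empty((n, L, 4))
        a = _PRIOR4 * e[:, 0]
        s = a.sum(1, keepdims=True)
        if np.any(s <= 0):
            j = int(np.argwhere(s.ravel() <= 0)[0])
            raise ValueError(
                f"individual {self.individuals[j]!r} has zero-probability "
                f"marker data on chromosome {self.chrom.name!r}"
            )
        alpha[:, 0] = a / s
        for k in range(1, L):
            a = np.einsum("ni,ij->nj", alpha[:, k - 1], self.transitions[k - 1])
            a = a * e[:, k]
            s = a.sum(1, keepdims=True)
            if np.any(s <= 0):
                j = int(np.argwhere(s.ravel() <= 0)[0])
                raise ValueError(
                    f"individual {self.individuals[j]!r} has contradictory "
                    f"marker data near {self.positions[k]} cM on chromosome "
                    f"{self.chrom.name!r}"
                )
            alpha[:, k] = a / s
        beta[:, L - 1] = 1.0
        for k in range(L - 2, -1, -1):
            b = np.einsum("ij,nj->ni", self.transitions[k],
                          beta[:, k + 1] * e[:, k + 1])
            beta[:, k] = b / b.sum(1, keepdims=True)
        self._alpha, self._beta = alpha, beta

    def posteriors(self) -> np.ndarray:
        """Posterior ordered-state probabilities, shape (n, L, 4)."""
        self._run()
        post = self._alpha * self._beta
        return post / post.sum(2, keepdims=True)

    def pair_joint(self, posA: float, posB: float) -> np.ndarray:
        """Joint posterior of ordered states at two positions, (n, 4, 4).

        Axis 1 indexes the state at ``posA``, axis 2 at ``posB``.
        """
        iA, iB = self.locus_index(posA), self.locus_index(posB)
        if iA == iB:
            raise ValueError("pair_joint requires two distinct positions")
        if iA > iB:
            return np.swapaxes(self.pair_joint(posB, posA), 1, 2)
        self._run()
        n = self.emissions.shape[0]
        M = np.broadcast_to(np.eye(4), (n, 4, 4)).copy()
        for k in range(iA, iB):
            M = M @ self.transitions[k]
            if k + 1 < iB:
                M = M * self.emissions[:, k + 1][:, None, :]
        # emission at iB is in alpha? no: fold it here, beta excludes it
        M = M * self.emissions[:, iB][:, None, :]
        joint = self._alpha[:, iA][:, :, None] * M * self._beta[:, iB][:, None, :]
        s = joint.sum((1, 2), keepdims=True)
        return joint / s


def multipoint_qtl_probs(genotypes: GenotypeMatrix, lmap: LinkageMap,
                         chrom: str, position: float,
                         map_function: str = "kosambi") -> ConditionalProbMatrix:
    """Posterior QTL-genotype probabilities at one position.

    Convenience wrapper building a :class:`MultipointEngine` for a single
    query; use the engine directly for whole-grid scans.
    """
    cm = lmap.chromosome(chrom)
    eng = MultipointEngine(cm, genotypes, extra_positions=[position],
                           map_function=map_function)
    k = eng.locus_index(position)
    post = eng.posteriors()[:, [k], :]
    return ConditionalProbMatrix(chrom=chrom, positions=np.array([position]),
                                 probs4=post)


def grid_probs(genotypes: GenotypeMatrix, lmap: LinkageMap, grid: ScanGrid,
               map_function: str = "kosambi") -> dict[str, ConditionalProbMatrix]:
    """Posterior probabilities at every grid position, per chromosome."""
    out = {}
    for cname in grid.chromosomes:
        cm = lmap.chromosome(cname)
        pos = grid.positions[cname]
        eng = MultipointEngine(cm, genotypes, extra_positions=pos,
                               map_function=map_function)
        idx = [eng.locus_index(p) for p in pos]
        post = eng.posteriors()[:, idx, :]
        out[cname] = ConditionalProbMatrix(chrom=cname, positions=np.asarray(pos),
                                           probs4=post)
    return out


# ---------------------------------------------------------------------------
# scan grid


def insert_virtual_markers(lmap: LinkageMap, max_gap: float = 1.0) -> ScanGrid:
    """Densify the map with virtual markers so adjacent scan positions are
    at most ``max_gap`` cM apart.

    Virtual markers are treated as fully missing observations for every
    individual; each gap receives the minimal number of equally spaced
    insertions.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    chromosomes, positions, virtual = [], {}, {}
    for cm in lmap.chromosomes:
        pos, isv = [], []
        mp = np.asarray(cm.positions, dtype=float)
        for a, b in zip(mp[:-1], mp[1:]):
            pos.append(a)
            isv.append(False)
            gap = b - a
            if gap > max_gap + 1e-12:
                k = int(np.ceil(gap / max_gap)) - 1
                for t in range(1, k + 1):
                    pos.append(a + gap * t / (k + 1))
                    isv.append(True)
        pos.append(mp[-1])
        isv.append(False)
        chromosomes.append(cm.name)
        positions[cm.name] = np.asarray(pos)
        virtual[cm.name] = np.asarray(isv)
    return ScanGrid(chromosomes=chromosomes, positions=positions,
                    is_virtual=virtual)


# ---------------------------------------------------------------------------
# fitness at a scan position and probability correction


def position_fitness(sdl_params, sdl_positions, qtl_position,
                     qtl_chrom_same: bool = True,
                     map_function: str = "kosambi"):
    """Relative fitnesses of QTL-position genotypes induced by a linked
    SDL pair.

    A male gamete's survival is decided by its haplotype at the two SDL;
    the allele at the QTL position rides along through recombination.  The
    fitness triple equals the post-/pre-selection frequency ratio of the
    ordered QTL genotypes referenced to class AA, which under male-only
    selection reduces to f2 = f4 = q_q / q_Q (post-selection male allele
    frequencies at the position) and f3 = 1.

    When the QTL position coincides with an SDL this is exactly the
    marginal single-locus fitness; with the QTL unlinked from both SDL it
    tends to (1, 1, 1).  A QTL on another chromosome
    (``qtl_chrom_same=False``) returns the neutral triple.

    Parameters
    ----------
    sdl_params : object with attributes u, v, x
        Fitted viabilities (``ViabilityParams`` or an ``SdlFit``).
    sdl_positions : (float, float)
        SDL positions in cM, first position carries locus A.
    qtl_position : float
    """
    from .sdl_model import FitnessTriple

    if not qtl_chrom_same:
        return FitnessTriple(1.0, 1.0, 1.0)
    u, v, x = sdl_params.u, sdl_params.v, sdl_params.x
    pA, pB = float(sdl_positions[0]), float(sdl_positions[1])
    t = float(qtl_position)

    loci = [(pA, "S1"), (pB, "S2"), (t, "Q")]
    # the QTL may coincide with an SDL; drop the duplicate position
    if abs(t - pA) < 1e-9:
        loci = [(pA, "S1Q"), (pB, "S2")]
    elif abs(t - pB) < 1e-9:
        loci = [(pA, "S1"), (pB, "S2Q")]
    loci.sort(key=lambda lp: lp[0])
    pos = [lp[0] for lp in loci]
    labels = [lp[1] for lp in loci]
    rs = [r_from_d(b - a, map_function) for a, b in zip(pos[:-1], pos[1:])]

    iS1 = next(i for i, l in enumerate(labels) if l.startswith("S1"))
    iS2 = next(i for i, l in enumerate(labels) if l.startswith("S2"))
    iQ = next(i for i, l in enumerate(labels) if l.endswith("Q"))
    w_by_sdl = np.array([1.0, v, u, x])  # index 2*b_S1 + b_S2

    nloci = len(pos)
    qQ = qq = lam = 0.0
    for h in range(2 ** nloci):
        bits = [(h >> (nloci - 1 - i)) & 1 for i in range(nloci)]
        p = 0.5
        for i, r in enumerate(rs):
            p *= r if bits[i] != bits[i + 1] else 1 - r
        w = w_by_sdl[2 * bits[iS1] + bits[iS2]]
        lam += w * p
        if bits[iQ] == 0:
            qQ += w * p
        else:
            qq += w * p
    if lam <= 0:
        raise ZeroDivisionError("all male gametes are inviable")
    qQ, qq = qQ / lam, qq / lam
    if qQ <= 0:
        raise ZeroDivisionError(
            "reference allele at the QTL position has zero post-selection "
            "male frequency"
        )
    ratio = qq / qQ
    return FitnessTriple(f2=ratio, f3=1.0, f4=ratio)


def correct_conditional_probs(probs, fitness):
    """Reweight QTL-genotype probabilities by SDL-induced fitnesses.

    p*(QQ) : p*(Qq) : p*(qq) = p(QQ)*1 : p(Qq)*(f2+f3)/2 : p(qq)*f4,
    renormalized per individual.

    ``probs`` may be an (n, 3) array or a :class:`ConditionalProbMatrix`
    (whose internal 4-state rows are reweighted by (1, f2, f3, f4), which
    collapses to the same 3-class correction).
    """
    if fitness.f2 == fitness.f3 == fitness.f4 == 1.0:
        return probs  # bit-exact no-op: skip the renormalizing division
    if isinstance(probs, ConditionalProbMatrix):
        w4 = np.array([1.0, fitness.f2, fitness.f3, fitness.f4])
        new = probs.probs4 * w4
        s = new.sum(-1, keepdims=True)
        _check_rows(s, probs)
        return ConditionalProbMatrix(chrom=probs.chrom,
                                     positions=probs.positions,
                                     probs4=new / s)
    p = np.asarray(probs, dtype=float)
    w3 = np.array([1.0, fitness.het_weight(), fitness.f4])
    new = p * w3
    s = new.sum(-1, keepdims=True)
    _check_rows(s, None)
    return new / s


def _check_rows(s, cpm):
    if np.any(s <= 0):
        j = int(np.flatnonzero(s.reshape(s.shape[0], -1).min(1) <= 0)[0])
        who = "individual" if cpm is not None else "row"
        raise DegenerateCorrectionError(
            f"fitness correction left zero total probability ({who} {j})"
        )


def expected_dummies(probs: ConditionalProbMatrix) -> ExpectedDummies:
    """Expected additive/dominance regressors from genotype probabilities.

    The dummy coding is z = 1, 0, -1 and w = 0, 1, 0 for QQ, Qq, qq, so
    E[z] = p(QQ) - p(qq) and E[w] = p(Qq).
    """
    p3 = probs.probs3
    return ExpectedDummies(chrom=probs.chrom, positions=probs.positions,
                           z=p3[..., 0] - p3[..., 2], w=p3[..., 1])
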