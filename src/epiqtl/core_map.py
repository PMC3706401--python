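"""Linkage-map data model, genotype coding and map-function conversions.

Positions are genetic distances in centimorgans (cM) measured from the
first marker of each chromosome.  Distance <-> recombination-fraction
conversion uses the Kosambi map function throughout; Haldane is available
behind an explicit argument but is never the default.

Genotype observation codes (F2, codominant markers with dominant and
missing observations allowed):

    ========  =====  =======================================
    external  int    meaning
    ========  =====  =======================================
    ``AA``    0      homozygous for the P1 allele
    ``Aa``    1      heterozygous
    ``aa``    2      homozygous for the P2 allele
    ``A-``    3      dominant: carries A, i.e. not aa
    ``a-``    4      dominant: carries a, i.e. not AA
    ``-``     5      missing
    ========  =====  =======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CODE_TO_INT",
    "INT_TO_CODE",
    "ChromosomeMap",
    "LinkageMap",
    "GenotypeMatrix",
    "kosambi_r_from_d",
    "kosambi_d_from_r",
    "haldane_r_from_d",
    "haldane_d_from_r",
]

CODE_TO_INT = {"AA": 0, "Aa": 1, "aa": 2, "A-": 3, "a-": 4, "-": 5}
INT_TO_CODE = {v: k for k, v in CODE_TO_INT.items()}

#: codes that identify the underlying genotype class unambiguously
CODOMINANT_CODES = (0, 1, 2)


# ---------------------------------------------------------------------------
# map functions


def kosambi_r_from_d(d):
    """Recombination fraction from Kosambi map distance.

    Parameters
    ----------
    d : float or array_like
        Map distance in cM, ``d >= 0``.

    Returns
    -------
    r : float or ndarray
        ``r = tanh(2d/100) / 2``, in ``[0, 0.5)``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


def kosambi_d_from_r(r):
    """Kosambi map distance (cM) from recombination fraction ``0 <= r < 0.5``."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def haldane_r_from_d(d):
    """Recombination fraction from Haldane map distance (no interference)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def haldane_d_from_r(r):
    """Haldane map distance (cM) from recombination fraction."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


def r_from_d(d, map_function: str = "kosambi"):
    """Dispatch on the configured map function (``kosambi`` default)."""
    if map_function == "kosambi":
        return kosambi_r_from_d(d)
    if map_function == "haldane":
        return haldane_r_from_d(d)
    raise ValueError(f"unknown map function: {map_function!r}")


# ---------------------------------------------------------------------------
# linkage map


@dataclass
class ChromosomeMap:
    """Ordered markers on one chromosome with positions in cM."""

    name: str
    markers: list[str]
    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.markers) != self.positions.size:
            raise ValueError(
                f"chromosome {self.name!r}: {len(self.markers)} marker names "
                f"but {self.positions.size} positions"
            )
        if np.any(self.positions < 0):
            raise ValueError(f"chromosome {self.name!r}: negative position")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError(
                f"chromosome {self.name!r}: positions must be non-decreasing"
            )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.positions[0]), float(self.positions[-1])

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class LinkageMap:
    """A genetic map: one or more chromosomes of ordered markers.

    Marker names must be unique genome-wide.
    """

    chromosomes: list[ChromosomeMap] = field(default_factory=list)

    def __post_init__(self):
        names = self.marker_names()
        dupes = pd.Index(names)[pd.Index(names).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate marker names: {sorted(set(dupes))}")

    def marker_names(self) -> list[str]:
        return [m for c in self.chromosomes for m in c.markers]

    def n_markers(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def chromosome(self, name: str) -> ChromosomeMap:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")

    def marker_index(self) -> dict[str, tuple[str, float]]:
        """Map marker name -> (chromosome name, position)."""
        out = {}
        for c in self.chromosomes:
            for m, p in zip(c.markers, c.positions):
                out[m] = (c.name, float(p))
        return out


# ---------------------------------------------------------------------------
# genotype matrix


class GenotypeMatrix:
    """Individuals x markers table of F2 observation codes.

    Stored internally as an ``int8`` array with the fixed code mapping in
    :data:`CODE_TO_INT`.
    """

    def __init__(self, codes, individuals, markers):
        codes = np.asarray(codes)
        if codes.dtype.kind in "UO":
            codes = self._encode(codes, markers)
        codes = codes.astype(np.int8, copy=False)
        if codes.ndim != 2:
            raise ValueError("genotype codes must be a 2-D array")
        bad = (codes < 0) | (codes > 5)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code at individual {individuals[i]!r}, "
                f"marker {markers[j]!r}"
            )
        if codes.shape != (len(individuals), len(markers)):
            raise ValueError(
                f"code array shape {codes.shape} does not match "
                f"{len(individuals)} individuals x {len(markers)} markers"
            )
        self.codes = codes
        self.individuals = list(individuals)
        self.markers = list(markers)

    @staticmethod
    def _encode(strings, markers) -> np.ndarray:
        out = np.empty(strings.shape, dtype=np.int8)
        it = np.nditer(strings, flags=["multi_index", "refs_ok"])
        for cell in it:
            s = str(cell)
            if s not in CODE_TO_INT:
                i, j = it.multi_index
                raise ValueError(
                    f"unknown genotype code {s!r} at row {i + 1}, "
                    f"column {markers[j]!r}"
                )
            out[it.multi_index] = CODE_TO_INT[s]
        return out

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def column(self, marker: str) -> np.ndarray:
        return self.codes[:, self.markers.index(marker)]

    def subset_markers(self, names) -> "GenotypeMatrix":
        idx = [self.markers.index(m) for m in names]
        return GenotypeMatrix(self.codes[:, idx], self.individuals, list(names))

    def to_frame(self) -> pd.DataFrame:
        decoded = np.vectorize(INT_TO_CODE.get)(self.codes)
        return pd.DataFrame(decoded, index=self.individuals, columns=self.markers)

    def validate_against(self, lmap: LinkageMap, n_phenotypes: int | None = None):
        """Check dimensional consistency with a map (and phenotype length)."""
        if self.n_markers != lmap.n_markers():
            raise ValueError(
                f"genotype matrix has {self.n_markers} markers but the map "
                f"has {lmap.n_markers()}"
            )
        if set(self.markers) != set(lmap.marker_names()):
            missing = set(lmap.marker_names()) - set(self.markers)
            raise ValueError(f"markers absent from genotype matrix: {sorted(missing)}")
        if n_phenotypes is not None and n_phenotypes != self.n_individuals:
            raise ValueError(
                f"{n_phenotypes} phenotypes for {self.n_individuals} individuals"
            )
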