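"""Natural-abundance correction of 13C tracer mass-distribution vectors.

A mass-distribution vector (MDV) holds the fractional abundances of a
metabolite fragment's isotopologues M+0..M+n, where n is the number of
tracer-element (carbon, by default) atoms in the fragment.  Raw MDVs
measured after a 13C6-glucose labeling experiment are convolved with the
natural isotope distributions of every atom in the fragment; correction
deconvolves that contribution to recover the tracer-derived labeling.

The correction matrix column k is the mass distribution expected when
exactly k tracer atoms carry label: a binomial 13C distribution over the
n-k unlabeled carbons, convolved with the natural mass-isotope
distributions of all non-tracer atoms, shifted by k and truncated to the
measured mass range M+0..M+n.  Correction solves ``matrix @ x = observed``
by nonnegative least squares and renormalizes, so measurement noise can
never produce negative isotopologue fractions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "MDV",
    "NATURAL_ABUNDANCES",
    "parse_formula",
    "build_correction_matrix",
    "correct_mdv",
    "fractional_contribution",
    "total_labeled",
]

# Isotope mass distributions per element, index = mass shift in Da.
# IUPAC representative isotopic compositions.
NATURAL_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "P": (1.0,),
    "Si": (0.92223, 0.04685, 0.03092),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict[str, int]) -> dict[str, int]:
    """Parse 'C3H7NO3'-style strings into an element -> count map."""
    if isinstance(formula, dict):
        counts = {str(k): int(v) for k, v in formula.items()}
    else:
        counts = {}
        pos = 0
        for match in _FORMULA_RE.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            element = match.group(1)
            counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
    for element, n in counts.items():
        if n < 0:
            raise ValueError(f"negative atom count for {element}")
    return counts


@dataclass(frozen=True)
class MDV:
    """Mass-distribution vector for one metabolite fragment."""

    metabolite: str
    formula: str
    values: np.ndarray
    corrected: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("MDV values must be a 1-D vector")
        if (values < -1e-12).any():
            raise ValueError(f"{self.metabolite}: negative isotopologue fractions")
        if abs(values.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"{self.metabolite}: MDV must sum to 1 (got {values.sum():.8f})"
            )
        n_tracer = parse_formula(self.formula).get(_TRACER_DEFAULT, 0)
        if len(values) != n_tracer + 1:
            raise ValueError(
                f"{self.metabolite}: expected {n_tracer + 1} isotopologues for "
                f"formula {self.formula}, got {len(values)}"
            )

    @property
    def n_tracer_atoms(self) -> int:
        return len(self.values) - 1


_TRACER_DEFAULT = "C"


def _element_distribution(element: str, n_atoms: int, abundances) -> np.ndarray:
    """Mass distribution of n_atoms atoms of one element (self-convolution)."""
    try:
        base = np.asarray(abundances[element], dtype=float)
    except KeyError:
        raise ValueError(f"unknown element symbol {element!r}") from None
    total = base.sum()
    if total <= 0:  # all-zero abundance row: treat as monoisotopic
        base = np.array([1.0])
    else:
        base = base / total
    dist = np.array([1.0])
    for _ in range(n_atoms):
        dist = np.convolve(dist, base)
    return dist


def build_correction_matrix(
    formula: str | dict[str, int],
    abundance_table: dict[str, tuple[float, ...]] | None = None,
    tracer: str = "C",
    renormalize_columns: bool = False,
) -> np.ndarray:
    """Correction matrix for the fragment with the given elemental formula.

    Column k holds the observed mass distribution (truncated to M+0..M+n)
    when exactly k of the n tracer atoms are isotopically labeled.  By
    default the truncation deficit is left in place (columns sum to <= 1);
    ``renormalize_columns=True`` rescales each column to sum to 1.
    """
    counts = parse_formula(formula)
    abundances = dict(NATURAL_ABUNDANCES)
    if abundance_table:
        for element, dist in abundance_table.items():
            abundances[element] = tuple(float(x) for x in dist)
    n = counts.get(tracer, 0)
    if n < 1:
        raise ValueError(f"formula must contain at least one {tracer} atom")

    # Mass distribution contributed by all non-tracer atoms.
    other = np.array([1.0])
    for element, n_atoms in counts.items():
        if element == tracer:
            continue
        other = np.convolve(other, _element_distribution(element, n_atoms, abundances))

    tracer_nat = np.asarray(abundances[tracer], dtype=float)
    tracer_nat = tracer_nat / tracer_nat.sum() if tracer_nat.sum() > 0 else np.array([1.0])

    matrix = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        # Unlabeled tracer atoms follow natural abundance; labeled ones
        # contribute a fixed +k mass shift.
        unlabeled = _element_distribution(tracer, n - k, {tracer: tracer_nat})
        column = np.convolve(unlabeled, other)
        shifted = np.zeros(n + 1)
        top = min(n + 1 - k, len(column))
        if top > 0:
            shifted[k : k + top] = column[:top]
        if renormalize_columns and shifted.sum() > 0:
            shifted = shifted / shifted.sum()
        matrix[:, k] = shifted
    return matrix


def correct_mdv(observed: MDV, matrix: np.ndarray | None = None, **matrix_kwargs) -> MDV:
    """Remove natural-isotope contributions from an observed MDV.

    Solves ``matrix @ x = observed.values`` by NNLS and renormalizes x to
    sum to 1.  The matrix is built from the MDV's formula when not given.
    """
    if observed.corrected:
        raise ValueError(f"{observed.metabolite}: MDV is already corrected")
    if matrix is None:
        matrix = build_correction_matrix(observed.formula, **matrix_kwargs)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(observed.values),) * 2:
        raise ValueError(
            f"matrix shape {matrix.shape} does not match MDV of length "
            f"{len(observed.values)}"
        )
    try:
        x, residual = nnls(matrix, observed.values)
    except RuntimeError as err:  # pragma: no cover - scipy iteration cap
        raise RuntimeError(f"NNLS failed to converge: {err}") from err
    if x.sum() <= 0:
        raise RuntimeError(
            f"{observed.metabolite}: degenerate NNLS solution (residual {residual:.3g})"
        )
    return replace(observed, values=x / x.sum(), corrected=True)


def fractional_contribution(mdv: MDV) -> float:
    """Average labeled fraction of tracer atoms: sum(i * m_i) / n."""
    if not mdv.corrected:
        raise ValueError(
            f"{mdv.metabolite}: fractional contribution requires a corrected MDV"
        )
    n = mdv.n_tracer_atoms
    weights = np.arange(n + 1)
    return float((weights * mdv.values).sum() / n)


def total_labeled(mdv: MDV) -> float:
    """Summed fraction of all labeled isotopologues, M+1..M+n."""
    if not mdv.corrected:
        raise ValueError(f"{mdv.metabolite}: total labeled requires a corrected MDV")
    return float(mdv.values[1:].sum())
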