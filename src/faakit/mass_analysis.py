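"""Theoretical masses and mixture-model peak calling for oligomer-state assays.

Mass photometry reports one mass per landing event; oligomeric species appear
as roughly Gaussian populations.  This module computes the reference masses
those populations are compared against — average protein masses from sequence,
noncovalent assembly (oligomer/heterocomplex) masses, and monoisotopic
condensation-product masses (acid + amine - water) for LC-MS ion matching —
and calls populations on event lists with a seeded one-dimensional Gaussian
mixture fitted by expectation-maximisation.

Events below the instrument's quantitative detection floor (default 30 kDa;
small carrier proteins near 10 kDa ratiometrically register as unreliable
signals around 30 kDa) are excluded before fitting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "MONOISOTOPIC_ELEMENT_MASS",
    "PopulationFit",
    "NonConvergenceError",
    "parse_formula",
    "formula_monoisotopic_mass",
    "protein_average_mass",
    "oligomer_mass",
    "amide_product_mass",
    "fit_populations",
    "read_events",
    "histogram_export",
]

#: Average residue (amino acid minus water) masses in Da, standard values
#: computed from IUPAC 2021 standard atomic weights.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_AVERAGE = 18.01528  # Da

#: Monoisotopic atomic masses (Da) of the lightest stable isotope.
MONOISOTOPIC_ELEMENT_MASS = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
}
WATER_MONOISOTOPIC = 2 * MONOISOTOPIC_ELEMENT_MASS["H"] + MONOISOTOPIC_ELEMENT_MASS["O"]


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula like ``"C18H34O2"``."""
    counts: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_monoisotopic_mass(formula: dict[str, int] | str) -> float:
    """Monoisotopic mass (Da) of a molecular formula."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    mass = 0.0
    for element, count in formula.items():
        if count <= 0:
            raise ValueError(f"element count must be positive ({element}: {count})")
        try:
            mass += MONOISOTOPIC_ELEMENT_MASS[element] * count
        except KeyError:
            raise ValueError(
                f"no monoisotopic mass for element {element!r}"
            ) from None
    return mass


def protein_average_mass(sequence: str) -> float:
    """Average mass of a protein in kDa: sum of residue masses plus one water."""
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    bad = [
        f"{res}@{i + 1}"
        for i, res in enumerate(sequence)
        if res not in AVERAGE_RESIDUE_MASS
    ]
    if bad:
        raise ValueError(f"non-canonical residues: {', '.join(bad)}")
    da = sum(AVERAGE_RESIDUE_MASS[r] for r in sequence) + WATER_AVERAGE
    return da / 1000.0


def oligomer_mass(component_masses, stoichiometry) -> float:
    """Mass (kDa) of a noncovalent assembly: sum of stoichiometry x mass.

    No water correction: assembly is noncovalent, unlike peptide-bond
    condensation.
    """
    masses = list(component_masses)
    stoich = list(stoichiometry)
    if len(masses) != len(stoich):
        raise ValueError("component_masses and stoichiometry differ in length")
    if any(m <= 0 for m in masses):
        raise ValueError("component masses must be positive")
    return float(sum(s * m for s, m in zip(stoich, masses)))


def amide_product_mass(
    acid: dict[str, int] | str, amine: dict[str, int] | str
) -> float:
    """Monoisotopic mass (Da) of the fatty-acid-amide condensation product.

    Amide-bond formation between a carboxylic acid and an amine releases one
    water: mass(acid) + mass(amine) - mass(H2O).
    """
    if isinstance(acid, str):
        acid = parse_formula(acid)
    if isinstance(amine, str):
        amine = parse_formula(amine)
    if acid.get("O", 0) < 1 or acid.get("H", 0) < 1:
        raise ValueError("acid must contain at least one O and one H to lose as water")
    if amine.get("N", 0) < 1:
        raise ValueError("amine must contain nitrogen")
    return (
        formula_monoisotopic_mass(acid)
        + formula_monoisotopic_mass(amine)
        - WATER_MONOISOTOPIC
    )


# ---------------------------------------------------------------------------
# Mixture-model population calling


@dataclass
class PopulationFit:
    """One fitted Gaussian population: mean/sd in kDa, event count, weight."""

    mean: float
    sd: float
    count: int
    weight: float


class NonConvergenceError(RuntimeError):
    def __init__(self, n_iter: int):
        super().__init__(f"EM did not converge within {n_iter} iterations")
        self.n_iter = n_iter


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding of component means on 1-D data."""
    centers = [x[rng.integers(x.size)]]
    for _ in range(1, k):
        d2 = np.min([(x - c) ** 2 for c in centers], axis=0)
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(x.size)])
        else:
            centers.append(rng.choice(x, p=d2 / total))
    return np.array(centers, float)


def fit_populations(
    events,
    k: int,
    seed: int,
    floor: float | None = 30.0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> list[PopulationFit]:
    """Fit a k-component Gaussian mixture to a mass-event list by EM.

    Events below ``floor`` (kDa) are excluded before fitting.  Means are
    seeded with k-means++ under the given ``seed``; EM iterates until the
    change in mean log-likelihood drops below ``tol`` (at most ``max_iter``
    iterations, else :class:`NonConvergenceError`).  Components are returned
    sorted by mean; ``count`` is the weight-apportioned number of retained
    events, rounded.
    """
    x = np.asarray(list(events), float)
    if not np.all(np.isfinite(x)):
        raise ValueError("events must be finite")
    if floor is not None:
        x = x[x >= floor]
    n = x.size
    if k < 1:
        raise ValueError("k must be at least 1")
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} retained events, got {n}")

    if k == 1:
        # Closed-form MLE; EM with one component converges here immediately.
        mean = float(x.mean())
        sd = float(x.std())
        return [PopulationFit(mean=mean, sd=sd, count=n, weight=1.0)]

    rng = np.random.default_rng(seed)
    means = _kmeanspp_init(x, k, rng)
    var0 = x.var()
    variances = np.full(k, var0 if var0 > 0 else 1.0)
    weights = np.full(k, 1.0 / k)
    var_floor = 1e-12

    prev_ll = -np.inf
    for _ in range(max_iter):
        # E step in log space
        log_pdf = (
            -0.5 * np.log(2 * np.pi * variances)[None, :]
            - (x[:, None] - means[None, :]) ** 2 / (2 * variances)[None, :]
        )
        log_joint = np.log(weights)[None, :] + log_pdf
        log_norm = logsumexp(log_joint, axis=1)
        resp = np.exp(log_joint - log_norm[:, None])
        ll = log_norm.mean()
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)
        weights = nk / n
    else:
        raise NonConvergenceError(max_iter)

    order = np.argsort(means)
    return [
        PopulationFit(
            mean=float(means[i]),
            sd=float(np.sqrt(variances[i])),
            count=int(round(weights[i] * n)),
            weight=float(weights[i]),
        )
        for i in order
    ]


# ---------------------------------------------------------------------------
# Event-list I/O


def read_events(path) -> list[float]:
    """Read masses (kDa) from a one-per-line text file or a single-column CSV."""
    events = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            value = ln.split(",")[0]
            if value.lower() in ("mass", "mass_kda"):
                continue
            events.append(float(value))
    if not events:
        raise ValueError(f"no events in {path}")
    return events


def histogram_export(events, bin_width: float = 2.0):
    """Histogram of events: (bin_edges, counts), for external plotting."""
    x = np.asarray(list(events), float)
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    return edges, counts
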