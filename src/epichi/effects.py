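"""Genotype-to-effect linear maps for multilocus quantitative genetics.

A biallelic locus has three genotype classes — both copies of the designated
("capital") allele, heterozygous, and neither copy — ordered ``AA, Aa, aa``.
Under the F-infinity (Mather–Jinks) metric the genotypic values at one locus
are parameterised by an overall mean ``mu``, an additive effect ``a`` (half
the difference between the homozygotes) and a dominance effect ``d`` (the
heterozygote's deviation from the homozygote midpoint)::

    G_AA = mu + a        G_Aa = mu + d        G_aa = mu - a

For ``n`` loci the 3**n genotypic values decompose into 3**n effects — the
mean, per-locus additive and dominance main effects, and epistatic
interactions of every order up to ``n`` (additive-by-additive,
additive-by-dominant, ..., dominant-by-...-by-dominant).  The map from
effects to genotypic values is the n-fold Kronecker product of the one-locus
3x3 design matrix, and its inverse (the "solver") is the Kronecker product of
the analytic one-locus inverse, so both are exact with dyadic-rational
entries.

Genotypes and effects share a base-3 flat indexing with locus 1 as the most
significant digit: genotype digits are ``0=AA, 1=Aa, 2=aa`` and effect digits
are ``0=mean, 1=additive, 2=dominant``.
"""

from __future__ import annotations

import enum
import functools
import string
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MAX_LOCI",
    "LocusComponent",
    "EffectLabel",
    "EffectDecomposition",
    "per_locus_design",
    "per_locus_solver",
    "build_decomposition",
    "decompose",
    "compose",
    "effect_label",
    "effect_index",
    "genotype_label",
    "genotype_index",
]

#: Largest locus count for which full 3**n x 3**n matrices are materialised.
MAX_LOCI = 8


class LocusComponent(enum.Enum):
    """The component a locus contributes to one effect term.

    ``MEAN`` means the locus does not participate in the term (it enters
    through its mean row only and adds nothing to the interaction order).
    """

    MEAN = "m"
    ADDITIVE = "a"
    DOMINANT = "d"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


#: Per-locus component order used for effect flat indices.
COMPONENT_ORDER: tuple[LocusComponent, ...] = (
    LocusComponent.MEAN,
    LocusComponent.ADDITIVE,
    LocusComponent.DOMINANT,
)

_CHAR_TO_COMPONENT = {c.value: c for c in COMPONENT_ORDER}


@functools.total_ordering
@dataclass(frozen=True)
class EffectLabel:
    """Identifies one genetic effect by its per-locus components.

    Parameters
    ----------
    components
        One :class:`LocusComponent` per locus, locus 1 first.

    Examples
    --------
    >>> lab = EffectLabel.from_pattern("dad")
    >>> lab.order, lab.dominance_count
    (3, 2)
    >>> lab.pattern
    'd*a*d'
    >>> lab.name
    'i_dad(A,B,C)'
    """

    components: tuple[LocusComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("an effect label needs at least one locus")
        for c in self.components:
            if not isinstance(c, LocusComponent):
                raise TypeError(f"not a LocusComponent: {c!r}")

    @classmethod
    def from_pattern(cls, pattern: str) -> "EffectLabel":
        """Parse ``"d*a*d"``, ``"dad"`` or ``"mu"`` into a label."""
        if pattern in ("mu", "μ"):
            raise ValueError("the overall mean needs an explicit locus count; "
                             "use EffectLabel.mean(n)")
        chars = pattern.replace("*", "")
        try:
            comps = tuple(_CHAR_TO_COMPONENT[ch] for ch in chars)
        except KeyError as exc:
            raise ValueError(f"invalid component character in {pattern!r}") from exc
        return cls(comps)

    @classmethod
    def mean(cls, n: int) -> "EffectLabel":
        """The all-MEAN label: the overall mean mu of an n-locus system."""
        return cls((LocusComponent.MEAN,) * n)

    @property
    def n(self) -> int:
        """Number of loci in the system the label lives in."""
        return len(self.components)

    @property
    def order(self) -> int:
        """Interaction order: number of loci contributing a non-mean component."""
        return sum(c is not LocusComponent.MEAN for c in self.components)

    @property
    def dominance_count(self) -> int:
        """Number of loci contributing through their dominance component."""
        return sum(c is LocusComponent.DOMINANT for c in self.components)

    @property
    def is_mean(self) -> bool:
        return self.order == 0

    @property
    def pattern(self) -> str:
        """Full per-locus rendering, e.g. ``'d*m*a'``."""
        return "*".join(c.value for c in self.components)

    @property
    def name(self) -> str:
        """Field-style name: ``mu``, ``a(B)``, ``i_dd(A,C)``, ``i_aaa(A,B,C)``."""
        if self.is_mean:
            return "mu"
        letters = string.ascii_uppercase
        active = [(letters[i], c.value)
                  for i, c in enumerate(self.components)
                  if c is not LocusComponent.MEAN]
        loci = ",".join(l for l, _ in active)
        if self.order == 1:
            return f"{active[0][1]}({loci})"
        comps = "".join(c for _, c in active)
        return f"i_{comps}({loci})"

    def __str__(self) -> str:
        return "mu" if self.is_mean else self.pattern

    def __lt__(self, other: "EffectLabel") -> bool:
        return effect_index(self) < effect_index(other)


def per_locus_design() -> np.ndarray:
    """One-locus design matrix L (rows AA, Aa, aa; columns mu, a, d).

    ``L @ (mu, a, d) = (G_AA, G_Aa, G_aa)`` under the F-infinity metric.
    """
    return np.array([[1.0, 1.0, 0.0],
                     [1.0, 0.0, 1.0],
                     [1.0, -1.0, 0.0]])


def per_locus_solver() -> np.ndarray:
    """Analytic inverse of :func:`per_locus_design` (rows mu, a, d)."""
    return np.array([[0.5, 0.0, 0.5],
                     [0.5, 0.0, -0.5],
                     [-0.5, 1.0, -0.5]])


@dataclass(frozen=True)
class EffectDecomposition:
    """The exact 3**n x 3**n genotype<->effect linear maps for n loci.

    Attributes
    ----------
    n
        Locus count.
    design
        Genotypes-by-effects matrix S with entries in {-1, 0, +1};
        ``values = design @ effects``.
    solver
        Its inverse, entries integer multiples of (1/2)**n;
        ``effects = solver @ values``.
    """

    n: int
    design: np.ndarray
    solver: np.ndarray

    @property
    def size(self) -> int:
        return 3 ** self.n

    def effect_labels(self) -> list[EffectLabel]:
        """All 3**n labels in flat-index order."""
        return [effect_label(i, self.n) for i in range(self.size)]


@functools.lru_cache(maxsize=None)
def build_decomposition(n: int, max_loci: int = MAX_LOCI) -> EffectDecomposition:
    """Build the n-locus decomposition as Kronecker powers of the 3x3 maps.

    Raises
    ------
    ValueError
        If ``n`` is outside ``[1, max_loci]`` (3**8 = 6561 rows is the
        default cap; beyond that the dense matrices get unwieldy).
    """
    if not 1 <= n <= max_loci:
        raise ValueError(f"locus count must be in [1, {max_loci}], got {n}")
    design = per_locus_design()
    solver = per_locus_solver()
    S, Sinv = design, solver
    for _ in range(n - 1):
        S = np.kron(S, design)
        Sinv = np.kron(Sinv, solver)
    S.setflags(write=False)
    Sinv.setflags(write=False)
    return EffectDecomposition(n=n, design=S, solver=Sinv)


def _infer_n(length: int) -> int:
    n = round(np.log(length) / np.log(3))
    if 3 ** n != length:
        raise ValueError(f"vector length {length} is not a power of 3")
    return n


def decompose(values: np.ndarray, n: int | None = None) -> np.ndarray:
    """Solve the effect vector from a genotypic-value vector.

    Parameters
    ----------
    values
        Length 3**n vector of genotypic values in genotype flat-index order.
    n
        Locus count; inferred from the length when omitted.

    Returns
    -------
    numpy.ndarray
        Effect vector in effect flat-index order (entry 0 is mu).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-d genotypic-value vector")
    if n is None:
        n = _infer_n(values.size)
    elif values.size != 3 ** n:
        raise ValueError(f"expected length {3 ** n} for n={n}, got {values.size}")
    return build_decomposition(n).solver @ values


def compose(effects: np.ndarray, n: int | None = None) -> np.ndarray:
    """Map an effect vector back to genotypic values (inverse of decompose)."""
    effects = np.asarray(effects, dtype=float)
    if effects.ndim != 1:
        raise ValueError("expected a 1-d effect vector")
    if n is None:
        n = _infer_n(effects.size)
    elif effects.size != 3 ** n:
        raise ValueError(f"expected length {3 ** n} for n={n}, got {effects.size}")
    return build_decomposition(n).design @ effects


def effect_label(flat_index: int, n: int) -> EffectLabel:
    """Label for a flat effect index (base-3, locus 1 most significant)."""
    if not 0 <= flat_index < 3 ** n:
        raise ValueError(f"effect index {flat_index} out of range for n={n}")
    digits = []
    x = flat_index
    for _ in range(n):
        digits.append(x % 3)
        x //= 3
    return EffectLabel(tuple(COMPONENT_ORDER[d] for d in reversed(digits)))


def effect_index(label: EffectLabel) -> int:
    """Flat index of an effect label (inverse of :func:`effect_label`)."""
    idx = 0
    for c in label.components:
        idx = idx * 3 + COMPONENT_ORDER.index(c)
    return idx


def genotype_label(flat_index: int, n: int) -> str:
    """Render a genotype flat index as e.g. ``'AaBBcc'`` (class 0=AA, 1=Aa, 2=aa)."""
    if not 0 <= flat_index < 3 ** n:
        raise ValueError(f"genotype index {flat_index} out of range for n={n}")
    digits = []
    x = flat_index
    for _ in range(n):
        digits.append(x % 3)
        x //= 3
    parts = []
    for locus, d in enumerate(reversed(digits)):
        upper = string.ascii_uppercase[locus]
        lower = upper.lower()
        parts.append((upper + upper, upper + lower, lower + lower)[d])
    return "".join(parts)


def genotype_index(label: str) -> int:
    """Flat index of a genotype string like ``'AaBBcc'``."""
    if len(label) % 2:
        raise ValueError(f"genotype label {label!r} must pair alleles")
    idx = 0
    for i in range(0, len(label), 2):
        pair = label[i:i + 2]
        n_upper = sum(ch.isupper() for ch in pair)
        idx = idx * 3 + (2 - n_upper)
    return idx
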