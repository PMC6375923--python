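"""Two-level fractional factorial and central composite designs.

Designs are held in a :class:`DesignTable`: a runs x factors matrix of
*coded* levels (factorial levels are -1/+1, centre rows all-zero, axial
rows +/-alpha on one factor) plus named response vectors.  All model
arithmetic downstream happens in coded units; :func:`code` /
:func:`decode` map between coded and natural factor settings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DesignConfigError(ValueError):
    """Raised for invalid design specifications (bad generator words, etc.)."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its natural low/high/centre levels."""

    name: str
    low_natural: float
    high_natural: float
    center_natural: float | None = None
    discrete: bool = False

    def __post_init__(self) -> None:
        if not self.low_natural < self.high_natural:
            raise ValueError(
                f"factor {self.name!r}: low ({self.low_natural}) must be "
                f"< high ({self.high_natural})"
            )
        center = self.center
        if not (self.low_natural <= center <= self.high_natural):
            raise ValueError(f"factor {self.name!r}: centre outside [low, high]")

    @property
    def center(self) -> float:
        if self.center_natural is not None:
            return self.center_natural
        return 0.5 * (self.low_natural + self.high_natural)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high_natural - self.low_natural)


@dataclass
class DesignTable:
    """Runs x factors coded design with attached response vectors."""

    factor_names: list[str]
    coded_matrix: np.ndarray
    run_ids: list[str] = field(default_factory=list)
    center_point_flags: np.ndarray | None = None
    responses: dict[str, np.ndarray] = field(default_factory=dict)
    alias_structure: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        self.coded_matrix = np.asarray(self.coded_matrix, dtype=float)
        n, k = self.coded_matrix.shape
        if k != len(self.factor_names):
            raise ValueError("coded_matrix width != number of factor names")
        if not self.run_ids:
            self.run_ids = [f"run{i + 1:02d}" for i in range(n)]
        if self.center_point_flags is None:
            self.center_point_flags = np.all(self.coded_matrix == 0.0, axis=1)
        self.center_point_flags = np.asarray(self.center_point_flags, dtype=bool)
        for name, y in self.responses.items():
            y = np.asarray(y, dtype=float)
            if y.shape != (n,):
                raise ValueError(f"response {name!r} must have one value per run")
            self.responses[name] = y

    @property
    def n_runs(self) -> int:
        return self.coded_matrix.shape[0]

    @property
    def factorial_mask(self) -> np.ndarray:
        """Rows belonging to the +/-1 factorial portion (not centre, not axial)."""
        is_pm1 = np.all(np.isin(self.coded_matrix, (-1.0, 1.0)), axis=1)
        return is_pm1 & ~self.center_point_flags

    def add_response(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_runs,):
            raise ValueError(f"response {name!r} must have one value per run")
        self.responses[name] = values

    def column(self, factor: str) -> np.ndarray:
        try:
            j = self.factor_names.index(factor)
        except ValueError as exc:
            raise KeyError(f"unknown factor {factor!r}") from exc
        return self.coded_matrix[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coded_matrix, columns=self.factor_names)
        df.insert(0, "run_id", self.run_ids)
        df.insert(1, "center_flag", self.center_point_flags.astype(int))
        for name, y in self.responses.items():
            df[name] = y
        return df


@dataclass(frozen=True)
class CCDSpec:
    """Central composite design geometry: 2^k factorial + 2k axial + centres."""

    n_factors: int = 2
    axial_distance: float = 1.414
    n_center: int = 3
    factor_specs: tuple[FactorSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.axial_distance <= 0:
            raise ValueError("axial distance alpha must be > 0")
        if self.n_factors < 1:
            raise ValueError("need at least one factor")


# ---------------------------------------------------------------------------
# Regular two-level fractions


def _parse_word(word: str, base: list[str]) -> frozenset[str]:
    letters = [ch for ch in word.upper() if not ch.isspace() and ch != "*"]
    unknown = [ch for ch in letters if ch not in base]
    if unknown:
        raise DesignConfigError(
            f"generator word {word!r} references non-base factors {unknown}"
        )
    # letters appearing an even number of times cancel
    out = frozenset(ch for ch in set(letters) if letters.count(ch) % 2 == 1)
    if not out:
        raise DesignConfigError(f"generator word {word!r} is empty after reduction")
    return out


def default_generators(n_factors: int, n_generators: int) -> list[str]:
    """Resolution-maximising generator words for common 2^(k-p) fractions."""
    table = {
        (7, 3): ["ABC", "BCD", "ACD"],   # E=ABC, F=BCD, G=ACD -> resolution IV
        (5, 1): ["ABCD"],
        (6, 2): ["ABC", "BCD"],
        (4, 1): ["ABC"],
    }
    try:
        return table[(n_factors, n_generators)]
    except KeyError as exc:
        raise DesignConfigError(
            f"no default generators for 2^({n_factors}-{n_generators}); "
            "pass generators explicitly"
        ) from exc


def _defining_relation(
    base: list[str], generated: list[str], words: list[frozenset[str]]
) -> list[frozenset[str]]:
    """All non-identity words of the defining contrast subgroup."""
    gen_words = [w | {g} for w, g in zip(words, generated)]
    subgroup: set[frozenset[str]] = {frozenset()}
    for gw in gen_words:
        subgroup |= {s ^ gw for s in subgroup}
    subgroup.discard(frozenset())
    return sorted(subgroup, key=lambda s: (len(s), sorted(s)))


def alias_chain(
    contrast: str, defining: list[frozenset[str]], max_order: int = 2
) -> list[str]:
    """Aliases of ``contrast`` up to ``max_order`` letters (excluding itself)."""
    w = frozenset(contrast.upper().replace("*", "").replace("×", ""))
    chains = sorted(
        ("".join(sorted(w ^ d)) for d in defining if 0 < len(w ^ d) <= max_order),
        key=lambda s: (len(s), s),
    )
    return chains


def build_fractional_factorial(
    n_factors: int,
    n_generators: int,
    generators: list[str] | None = None,
    n_center_replicates: int = 0,
    factor_names: list[str] | None = None,
) -> DesignTable:
    """Build a regular 2^(k-p) fraction in standard (Yates) order.

    The first ``n_factors - n_generators`` factors form the full factorial
    base; each remaining factor's column is the elementwise product of the
    base columns named by its generator word.  Centre replicates are
    appended as all-zero rows.
    """
    n_base = n_factors - n_generators
    if n_base < 2:
        raise DesignConfigError("need n_factors >= n_generators + 2")
    if factor_names is None:
        factor_names = [chr(ord("A") + i) for i in range(n_factors)]
    if len(factor_names) != n_factors:
        raise DesignConfigError("factor_names length != n_factors")
    base = factor_names[:n_base]
    generated = factor_names[n_base:]
    if n_generators:
        if generators is None:
            generators = default_generators(n_factors, n_generators)
        if len(generators) != n_generators:
            raise DesignConfigError("one generator word per generated factor")
        words = [_parse_word(w, base) for w in generators]
        if len(set(words)) != len(words):
            raise DesignConfigError("duplicated generator word")
    else:
        words = []

    # Yates order: first factor alternates fastest
    n_runs = 2 ** n_base
    cols = {}
    for i, name in enumerate(base):
        block = 2 ** i
        col = np.tile(np.repeat([-1.0, 1.0], block), n_runs // (2 * block))
        cols[name] = col
    for name, word in zip(generated, words):
        col = np.prod([cols[b] for b in sorted(word)], axis=0)
        for other, existing in cols.items():
            if np.array_equal(col, existing) or np.array_equal(col, -existing):
                raise DesignConfigError(
                    f"generated column {name!r} duplicates column {other!r}"
                )
        cols[name] = col

    matrix = np.column_stack([cols[f] for f in factor_names])
    if n_center_replicates:
        matrix = np.vstack([matrix, np.zeros((n_center_replicates, n_factors))])

    defining = _defining_relation(base, generated, words) if words else []
    aliases = {f: alias_chain(f, defining) for f in factor_names}
    flags = np.r_[np.zeros(n_runs, bool), np.ones(n_center_replicates, bool)]
    return DesignTable(
        factor_names=list(factor_names),
        coded_matrix=matrix,
        center_point_flags=flags,
        alias_structure=aliases,
    )


def build_central_composite(spec: CCDSpec) -> DesignTable:
    """2^k factorial + 2k axial (+/-alpha on one axis) + n_center centre runs."""
    import warnings

    k = spec.n_factors
    if k != 2:
        warnings.warn(
            f"central composite with k={k}; the reference workflow uses k=2",
            stacklevel=2,
        )
    names = (
        [fs.name for fs in spec.factor_specs]
        if spec.factor_specs
        else [f"X{i + 1}" for i in range(k)]
    )
    factorial = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    # match Yates convention of build_fractional_factorial: first factor fastest
    factorial = factorial[:, ::-1]
    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = spec.axial_distance
        axial[2 * i + 1, i] = -spec.axial_distance
    center = np.zeros((spec.n_center, k))
    matrix = np.vstack([factorial, axial, center])
    flags = np.r_[
        np.zeros(len(factorial) + len(axial), bool), np.ones(spec.n_center, bool)
    ]
    return DesignTable(
        factor_names=names, coded_matrix=matrix, center_point_flags=flags
    )


def shuffle_runs(design: DesignTable, seed: int) -> DesignTable:
    """Return a copy with run order randomized by ``seed``."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(design.n_runs)
    return DesignTable(
        factor_names=list(design.factor_names),
        coded_matrix=design.coded_matrix[order],
        run_ids=[design.run_ids[i] for i in order],
        center_point_flags=design.center_point_flags[order],
        responses={k: v[order] for k, v in design.responses.items()},
        alias_structure=design.alias_structure,
    )


# ---------------------------------------------------------------------------
# Coded <-> natural mapping


def code(natural: dict[str, float], specs: list[FactorSpec]) -> dict[str, float]:
    """Natural units -> coded units: (x - centre) / half_range."""
    by_name = {s.name: s for s in specs}
    out = {}
    for name, x in natural.items():
        if name not in by_name:
            raise KeyError(f"no FactorSpec for factor {name!r}")
        s = by_name[name]
        out[name] = (x - s.center) / s.half_range
    return out


def decode(coded: dict[str, float], specs: list[FactorSpec]) -> dict[str, float]:
    """Coded units -> natural units; exact inverse of :func:`code`."""
    by_name = {s.name: s for s in specs}
    out = {}
    for name, z in coded.items():
        if name not in by_name:
            raise KeyError(f"no FactorSpec for factor {name!r}")
        s = by_name[name]
        x = s.center + z * s.half_range
        out[name] = round(x) if s.discrete else x
    return out
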