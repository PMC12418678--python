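"""Slater-type atomic radial function databanks.

A databank stores, per element, the *density* expansions (not orbitals) of
the frozen spherical core and the neutral-atom spherical valence,

    rho(r) = sum_i c_i r^(n_i) exp(-zeta_i r)   [e / bohr^3],

plus one single-exponential deformation radial function per multipole
level l,

    R_l(r) = N r^(n_l) exp(-zeta_l r),  N = zeta_l^(n_l+3) / (n_l+2)!,

normalized so that integral R_l(r) r^2 dr = 1.  Published orbital tables
(Clementi-Roetti-like, Su-Coppens-Macchi-like) can be pre-squared into this
density schema offline; the embedded "synthetic" bank covers H, C, N, O,
Mg and Cl with physically plausible (not literature) exponents.

File schema (plain text, ``#`` comments)::

    ELEM <symbol> <Z> <n_core> <n_val> <lmax>
    CORE <coeff> <n> <zeta>          (zero or more)
    VAL  <coeff> <n> <zeta>          (one or more)
    DEF  l=<l> n=<n> zeta=<zeta>     (one per supported l)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.polynomial.legendre import leggauss

from .errors import CapabilityError, DatabankLookupError, ParseError, ValidationError

#: radial quadrature cutoff, bohr.  exp(-zeta*r) underflows long before this
#: for every physical zeta.
R_CUTOFF = 60.0

_QUAD_NODES, _QUAD_WEIGHTS = leggauss(400)


def _radial_quadrature(f, rmax: float = R_CUTOFF) -> float:
    """integral_0^rmax f(r) dr by fixed high-order Gauss-Legendre."""
    r = 0.5 * rmax * (_QUAD_NODES + 1.0)
    w = 0.5 * rmax * _QUAD_WEIGHTS
    return float(np.sum(w * f(r)))


@dataclass(frozen=True)
class SlaterTerm:
    """One c * r^n * exp(-zeta r) density term."""

    coeff: float
    n_power: int
    zeta: float

    def __post_init__(self):
        if self.zeta <= 0:
            raise ValidationError(f"Slater exponent must be positive, got {self.zeta}")
        if self.n_power < 0:
            raise ValidationError(f"Slater power must be >= 0, got {self.n_power}")

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        return self.coeff * r ** self.n_power * np.exp(-self.zeta * r)


@dataclass
class ElementEntry:
    """Core/valence density expansions and deformation radials of one element."""

    symbol: str
    atomic_number: int
    n_core: float
    n_val: float
    core_terms: tuple[SlaterTerm, ...]
    valence_terms: tuple[SlaterTerm, ...]
    deformation: dict[int, tuple[int, float]] = field(default_factory=dict)  # l -> (n_l, zeta_l)

    @property
    def lmax_supported(self) -> int:
        return max(self.deformation) if self.deformation else -1

    def validate(self, tol: float = 1e-6) -> None:
        if self.atomic_number <= 0:
            raise ValidationError(f"{self.symbol}: Z must be positive")
        for comp, terms, n_expected in (("core", self.core_terms, self.n_core),
                                        ("valence", self.valence_terms, self.n_val)):
            got = _radial_quadrature(
                lambda r: 4.0 * math.pi * r ** 2 * sum(t(r) for t in terms)
            ) if terms else 0.0
            if abs(got - n_expected) > tol:
                raise ValidationError(
                    f"{self.symbol} {comp} density integrates to {got:.8f}, "
                    f"expected {n_expected}")
        for l, (n_l, zeta_l) in self.deformation.items():
            if zeta_l <= 0:
                raise ValidationError(f"{self.symbol} l={l}: zeta must be positive")
            if l >= 1 and n_l < 1:
                raise ValidationError(
                    f"{self.symbol} l={l}: n_l >= 1 required so R_l(0) is finite")


@dataclass
class RadialDatabank:
    """Named mapping element symbol -> :class:`ElementEntry`."""

    name: str
    entries: dict[str, ElementEntry]

    def __getitem__(self, symbol: str) -> ElementEntry:
        try:
            return self.entries[symbol]
        except KeyError:
            raise DatabankLookupError(
                f"element {symbol!r} not in databank {self.name!r}") from None


def spherical_density(entry: ElementEntry, component: str, r) -> np.ndarray:
    """Spherical core or valence density of an entry at radius r (bohr)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValidationError("radius must be non-negative")
    if component == "core":
        terms = entry.core_terms
    elif component == "valence":
        terms = entry.valence_terms
    else:
        raise ValidationError(f"component must be 'core' or 'valence', got {component!r}")
    if not terms:
        return np.zeros_like(r)
    out = np.zeros_like(r)
    for t in terms:
        out += t(r)
    return out


def deformation_norm(n: int, zeta: float) -> float:
    """N = zeta^(n+3)/(n+2)! so that integral N r^(n+2) exp(-zeta r) dr = 1."""
    return zeta ** (n + 3) / math.factorial(n + 2)


def deformation_radial(entry: ElementEntry, l: int, r) -> np.ndarray:
    """Normalized deformation radial function R_l(r), bohr^-3."""
    if l not in entry.deformation:
        raise CapabilityError(
            f"{entry.symbol}: deformation level l={l} not supported "
            f"(lmax={entry.lmax_supported})")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValidationError("radius must be non-negative")
    n, zeta = entry.deformation[l]
    return deformation_norm(n, zeta) * r ** n * np.exp(-zeta * r)


# ----------------------------------------------------------------------------
# entry construction helpers and built-in banks
# ----------------------------------------------------------------------------

def _density_terms(n_electrons: float, shells: list[tuple[float, int, float]]):
    """Build normalized density terms from (fraction, n, zeta) shells."""
    terms = []
    for frac, n, zeta in shells:
        c = frac * n_electrons * zeta ** (n + 3) / (4.0 * math.pi * math.factorial(n + 2))
        terms.append(SlaterTerm(c, n, zeta))
    return tuple(terms)


def _make_entry(symbol, Z, n_core, n_val, core_shells, val_shells,
                def_zeta, lmax, h_like=False):
    # conventional single-zeta deformation powers n_l; H uses (1, 2)
    n_l = {0: 2, 1: 1 if h_like else 2, 2: 2, 3: 3, 4: 4}
    deformation = {l: (n_l[l], def_zeta) for l in range(0, lmax + 1)}
    entry = ElementEntry(
        symbol=symbol, atomic_number=Z, n_core=n_core, n_val=n_val,
        core_terms=_density_terms(n_core, core_shells) if n_core else (),
        valence_terms=_density_terms(n_val, val_shells),
        deformation=deformation)
    entry.validate()
    return entry


def _builtin_synthetic() -> RadialDatabank:
    """Embedded synthetic bank for H, C, N, O, Mg, Cl.

    Exponents are plausible effective values (density exponent = twice an
    orbital zeta), not published Clementi-Roetti or Su-Coppens-Macchi data.
    """
    e = {}
    e["H"] = _make_entry("H", 1, 0.0, 1.0, [], [(1.0, 0, 2.0)],
                         def_zeta=2.0, lmax=2, h_like=True)
    # second-row valence = squared node-less 2s/2p STOs (r e^(-zeta r)),
    # hence pure r^2 e^(-2 zeta r) density terms: no cusp at the nucleus
    e["C"] = _make_entry("C", 6, 2.0, 4.0, [(1.0, 0, 11.3)],
                         [(1.0, 2, 3.2)], def_zeta=3.0, lmax=4)
    e["N"] = _make_entry("N", 7, 2.0, 5.0, [(1.0, 0, 13.3)],
                         [(1.0, 2, 3.8)], def_zeta=3.5, lmax=4)
    e["O"] = _make_entry("O", 8, 2.0, 6.0, [(1.0, 0, 15.2)],
                         [(1.0, 2, 4.4)], def_zeta=4.0, lmax=4)
    e["Mg"] = _make_entry("Mg", 12, 10.0, 2.0,
                          [(0.2, 0, 22.7), (0.8, 2, 7.4)],
                          [(1.0, 4, 2.4)], def_zeta=2.2, lmax=4)
    e["Cl"] = _make_entry("Cl", 17, 10.0, 7.0,
                          [(0.2, 0, 32.3), (0.8, 2, 13.0)],
                          [(0.3, 2, 4.4), (0.7, 4, 4.9)], def_zeta=4.0, lmax=4)
    return RadialDatabank("synthetic", e)


def _builtin_hydrogenic() -> RadialDatabank:
    """H only, rho_val(r) = exp(-2r)/pi (textbook 1s density)."""
    entry = _make_entry("H", 1, 0.0, 1.0, [], [(1.0, 0, 2.0)],
                        def_zeta=2.0, lmax=2, h_like=True)
    return RadialDatabank("hydrogenic-test", {"H": entry})


_BUILTINS = {"synthetic": _builtin_synthetic, "hydrogenic-test": _builtin_hydrogenic}


def load_databank(source) -> RadialDatabank:
    """Load a databank from a built-in name or a schema file path."""
    if isinstance(source, str) and source in _BUILTINS:
        return _BUILTINS[source]()
    path = Path(source)
    if not path.exists():
        raise ParseError(f"databank source {source!r} is neither a built-in "
                         f"({sorted(_BUILTINS)}) nor an existing file")
    return _parse_databank_file(path)


def _parse_databank_file(path: Path) -> RadialDatabank:
    entries: dict[str, ElementEntry] = {}
    current = None  # mutable accumulator

    def flush():
        nonlocal current
        if current is None:
            return
        entry = ElementEntry(
            symbol=current["symbol"], atomic_number=current["Z"],
            n_core=current["n_core"], n_val=current["n_val"],
            core_terms=tuple(current["core"]), valence_terms=tuple(current["val"]),
            deformation=current["def"])
        entry.validate()
        entries[entry.symbol] = entry
        current = None

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        try:
            tag = tokens[0].upper()
            if tag == "ELEM":
                flush()
                current = {"symbol": tokens[1], "Z": int(tokens[2]),
                           "n_core": float(tokens[3]), "n_val": float(tokens[4]),
                           "lmax": int(tokens[5]), "core": [], "val": [], "def": {}}
            elif tag in ("CORE", "VAL"):
                term = SlaterTerm(float(tokens[1]), int(tokens[2]), float(tokens[3]))
                current["core" if tag == "CORE" else "val"].append(term)
            elif tag == "DEF":
                kv = dict(t.split("=") for t in tokens[1:])
                current["def"][int(kv["l"])] = (int(kv["n"]), float(kv["zeta"]))
            else:
                raise ParseError(f"unknown record {tag!r}")
        except ValidationError:
            raise
        except ParseError:
            raise ParseError(f"{path}:{lineno}: unknown record {tokens[0]!r}") from None
        except Exception as exc:
            raise ParseError(f"{path}:{lineno}: malformed line {raw!r} ({exc})") from None
    flush()
    if not entries:
        raise ParseError(f"{path}: no ELEM blocks found")
    return RadialDatabank(path.stem, entries)


def write_databank(databank: RadialDatabank, path) -> None:
    """Write a databank in the plain-text schema (round-trips with load)."""
    lines = [f"# mmfit radial databank: {databank.name}"]
    for entry in databank.entries.values():
        lines.append(f"ELEM {entry.symbol} {entry.atomic_number} "
                     f"{float(entry.n_core)!r} {float(entry.n_val)!r} "
                     f"{entry.lmax_supported}")
        for t in entry.core_terms:
            lines.append(f"CORE {float(t.coeff)!r} {t.n_power} {float(t.zeta)!r}")
        for t in entry.valence_terms:
            lines.append(f"VAL {float(t.coeff)!r} {t.n_power} {float(t.zeta)!r}")
        for l in sorted(entry.deformation):
            n, zeta = entry.deformation[l]
            lines.append(f"DEF l={l} n={n} zeta={float(zeta)!r}")
    Path(path).write_text("\n".join(lines) + "\n")
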