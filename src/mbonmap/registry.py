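"""Driver-line registry and mushroom-body compartment bookkeeping.

The packaged registry lists the split-GAL4 driver lines used to initiate
transsynaptic tracing from MBONs: 28 previously published lines of which
three are excluded (two for weak signal, one for noisy signal, leaving 25
analyzed), plus three newer SS-series lines flagged
``previously_published=False``.

Compartment names are stored in an ASCII transliteration (``gamma2alphaP1``
for γ2α′1: Greek letter spelled out, prime written ``P``) because prime and
Greek glyphs travel badly through file formats; :func:`to_unicode` renders
the display form.  Feedforward MBON names such as ``gamma4>gamma1gamma2``
(dendrites in γ4, axons in γ1γ2) contribute their *dendritic* compartment to
the census, which is what makes the lobe census come out at the canonical
15 compartments (γ1–γ5, β1–β2, β′1–β′2, α1–α3, α′1–α′3).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "DriverLine",
    "load_registry",
    "apply_exclusions",
    "list_compartments",
    "compartments_of",
    "to_unicode",
    "CANONICAL_COMPARTMENTS",
    "NEUROTRANSMITTERS",
    "EXCLUSION_REASONS",
]

NEUROTRANSMITTERS = {"glutamatergic", "GABAergic", "cholinergic", "mixed/unknown"}
EXCLUSION_REASONS = {"none", "weak_signal", "noisy_signal"}

#: Lobe compartments in canonical order (γ, β, β′, α, α′ families).
CANONICAL_COMPARTMENTS = [
    "gamma1", "gamma2", "gamma3", "gamma4", "gamma5",
    "beta1", "beta2", "betaP1", "betaP2",
    "alpha1", "alpha2", "alpha3",
    "alphaP1", "alphaP2", "alphaP3",
]

_GREEK = {"gamma": "γ", "beta": "β", "alpha": "α"}
_COMPARTMENT_RE = re.compile(r"(gamma|beta|alpha)(P?)([1-5])")
#: tokens that name structures outside the 15 lobe compartments
_NON_LOBE_TOKENS = {"calyx"}


@dataclass
class DriverLine:
    line_id: str
    mbon_composition: list[tuple[str, int]]  # (MBON name, relative expression 1-5)
    neurotransmitter: str
    excluded: bool = False
    exclusion_reason: str = "none"
    previously_published: bool = True
    provenance: str = "transcribed"

    def __post_init__(self) -> None:
        if self.neurotransmitter not in NEUROTRANSMITTERS:
            raise ValueError(
                f"{self.line_id}: unknown neurotransmitter {self.neurotransmitter!r}")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(
                f"{self.line_id}: unknown exclusion reason {self.exclusion_reason!r}")
        if self.excluded != (self.exclusion_reason != "none"):
            raise ValueError(
                f"{self.line_id}: excluded flag inconsistent with reason "
                f"{self.exclusion_reason!r}")
        for name, expr in self.mbon_composition:
            if not 1 <= expr <= 5:
                raise ValueError(
                    f"{self.line_id}: relative expression {expr} outside 1..5 "
                    f"for {name!r}")


def to_unicode(ascii_name: str) -> str:
    """Render an ASCII compartment/MBON name with Greek letters and primes."""
    out = ascii_name
    for latin, greek in _GREEK.items():
        out = out.replace(latin, greek)
    return out.replace("P", "′")


def compartments_of(mbon_name: str) -> list[str]:
    """Dendritic lobe compartments named by one MBON token.

    ``gamma5betaP2a`` -> [gamma5, betaP2]; feedforward names keep only the
    part before ``>``; modifier suffixes (``a``, ``mp``, ``sc``, ``p3p`` ...)
    are ignored; non-lobe structures (calyx) yield nothing.
    """
    dendritic = mbon_name.split(">")[0].strip()
    if dendritic in _NON_LOBE_TOKENS:
        return []
    found = [f"{m.group(1)}{m.group(2)}{m.group(3)}"
             for m in _COMPARTMENT_RE.finditer(dendritic)]
    if not found:
        raise ValueError(f"unparseable MBON compartment token: {mbon_name!r}")
    seen: list[str] = []
    for c in found:
        if c not in seen:
            seen.append(c)
    return seen


def _parse_composition(text: str, line_id: str) -> list[tuple[str, int]]:
    comp: list[tuple[str, int]] = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        if ":" not in token:
            raise ValueError(f"{line_id}: malformed composition token {token!r}")
        name, expr = token.rsplit(":", 1)
        comp.append((name.strip(), int(expr)))
    if not comp:
        raise ValueError(f"{line_id}: empty MBON composition")
    return comp


def _packaged_table() -> pd.DataFrame:
    with resources.files("mbonmap.data").joinpath("driver_lines.csv").open() as fh:
        return pd.read_csv(fh)


def load_registry(table: pd.DataFrame | str | Path | None = None) -> list[DriverLine]:
    """Load driver lines from a table (default: the packaged registry).

    Fails fast with a row-level message on duplicate line ids, unknown
    neurotransmitter tokens, or inconsistent exclusion flags.
    """
    if table is None:
        df = _packaged_table()
    elif isinstance(table, (str, Path)):
        df = pd.read_csv(table)
    else:
        df = table.copy()
    required = {"line_id", "mbon_composition", "neurotransmitter"}
    if not required.issubset(df.columns):
        raise ValueError(f"registry table needs columns {sorted(required)}")
    dupes = df["line_id"][df["line_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate line_id rows: {sorted(set(dupes))}")

    lines: list[DriverLine] = []
    for _, row in df.iterrows():
        lines.append(DriverLine(
            line_id=str(row["line_id"]),
            mbon_composition=_parse_composition(row["mbon_composition"],
                                                str(row["line_id"])),
            neurotransmitter=str(row["neurotransmitter"]),
            excluded=bool(row.get("excluded", False)),
            exclusion_reason=str(row.get("exclusion_reason", "none")),
            previously_published=bool(row.get("previously_published", True)),
            provenance=str(row.get("provenance", "transcribed")),
        ))
    return lines


def apply_exclusions(registry: list[DriverLine]) -> list[DriverLine]:
    """Lines that survive quality exclusion, input order preserved."""
    return [line for line in registry if not line.excluded]


def list_compartments(registry: list[DriverLine]) -> list[str]:
    """Distinct dendritic lobe compartments across the registry, in
    canonical order (γ1…γ5, β1, β2, β′1, β′2, α1–α3, α′1–α′3)."""
    present: set[str] = set()
    for line in registry:
        for name, _ in line.mbon_composition:
            present.update(compartments_of(name))
    ordered = [c for c in CANONICAL_COMPARTMENTS if c in present]
    extra = sorted(present - set(CANONICAL_COMPARTMENTS))
    return ordered + extra
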