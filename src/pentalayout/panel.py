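"""Gene panel definition for the 19 GABA-A receptor subunit genes.

The panel carries, for every gene symbol, its subunit family and its
membership in one of the three stoichiometric sums used for the 2:2:1
pentamer gating (``SigmaAlpha``, ``SigmaBeta``, ``SigmaChi``); the three
rho genes are excluded from all sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

__all__ = [
    "GenePanel",
    "DEFAULT_SYMBOLS",
    "default_panel",
]

#: Canonical order of the 19 subunit genes.
DEFAULT_SYMBOLS: Tuple[str, ...] = (
    "GABRA1", "GABRA2", "GABRA3", "GABRA4", "GABRA5", "GABRA6",
    "GABRB1", "GABRB2", "GABRB3",
    "GABRD", "GABRE",
    "GABRG1", "GABRG2", "GABRG3",
    "GABRP", "GABRQ",
    "GABRR1", "GABRR2", "GABRR3",
)

_FAMILY_BY_PREFIX = {
    "GABRA": "alpha",
    "GABRB": "beta",
    "GABRG": "gamma",
    "GABRD": "delta",
    "GABRE": "epsilon",
    "GABRP": "pi",
    "GABRQ": "theta",
    "GABRR": "rho",
}

_SIGMA_ALPHA = {"GABRA1", "GABRA2", "GABRA3", "GABRA4", "GABRA5", "GABRA6"}
_SIGMA_BETA = {"GABRB1", "GABRB2", "GABRB3", "GABRQ"}
_SIGMA_CHI = {"GABRG1", "GABRG2", "GABRG3", "GABRD", "GABRE", "GABRP"}
_EXCLUDED = {"GABRR1", "GABRR2", "GABRR3"}


def _default_family(symbol: str) -> str:
    for prefix, fam in sorted(_FAMILY_BY_PREFIX.items(), key=lambda kv: -len(kv[0])):
        if symbol.startswith(prefix):
            return fam
    raise KeyError(f"no default family for symbol {symbol!r}")


def _default_sum_membership(symbol: str) -> str:
    if symbol in _SIGMA_ALPHA:
        return "SigmaAlpha"
    if symbol in _SIGMA_BETA:
        return "SigmaBeta"
    if symbol in _SIGMA_CHI:
        return "SigmaChi"
    if symbol in _EXCLUDED:
        return "excluded"
    raise KeyError(f"no default sum membership for symbol {symbol!r}")


@dataclass(frozen=True)
class GenePanel:
    """Ordered gene panel with family tags and stoichiometric-sum membership.

    Parameters
    ----------
    symbols
        Ordered, unique gene identifiers.
    family
        Mapping ``symbol -> family tag`` (alpha, beta, gamma, delta,
        epsilon, pi, theta, rho).
    sum_membership
        Mapping ``symbol -> one of {"SigmaAlpha", "SigmaBeta", "SigmaChi",
        "excluded"}``.
    """

    symbols: Tuple[str, ...]
    family: Dict[str, str] = field(default_factory=dict)
    sum_membership: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("panel symbols must be unique")
        try:
            fam = dict(self.family) or {s: _default_family(s) for s in self.symbols}
            mem = dict(self.sum_membership) or {
                s: _default_sum_membership(s) for s in self.symbols
            }
        except KeyError as exc:
            raise ValueError(str(exc)) from exc
        missing = [s for s in self.symbols if s not in fam or s not in mem]
        if missing:
            raise ValueError(f"panel annotations missing for: {missing}")
        bad = {m for m in mem.values()} - {
            "SigmaAlpha", "SigmaBeta", "SigmaChi", "excluded"
        }
        if bad:
            raise ValueError(f"invalid sum membership tags: {sorted(bad)}")
        object.__setattr__(self, "symbols", tuple(self.symbols))
        object.__setattr__(self, "family", fam)
        object.__setattr__(self, "sum_membership", mem)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)

    def members_of(self, sum_tag: str) -> List[str]:
        """Return panel symbols (in panel order) carrying ``sum_tag``."""
        return [s for s in self.symbols if self.sum_membership[s] == sum_tag]

    @property
    def pair_order(self) -> List[Tuple[str, str]]:
        """Canonical unordered gene pairs, ``n*(n-1)/2`` of them.

        Pairs follow panel order, which for the default panel is
        lexicographic.
        """
        syms = self.symbols
        return [
            (syms[i], syms[j])
            for i in range(len(syms))
            for j in range(i + 1, len(syms))
        ]


def default_panel() -> GenePanel:
    """The 19-gene GABA-A receptor subunit panel."""
    return GenePanel(symbols=DEFAULT_SYMBOLS)
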