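"""Anatomical ontology: substructure -> (structure, major region, origin, rank)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Optional

__all__ = ["OntologyEntry", "OntologyMap", "OntologyError", "default_ontology"]


class OntologyError(KeyError):
    """A substructure code does not resolve in the ontology."""


@dataclass(frozen=True)
class OntologyEntry:
    substructure: str
    structure: str
    major_region: str
    ontogenic_origin: str
    rostro_caudal_rank: int
    white_matter: bool = False


class OntologyMap:
    """Maps substructure codes to structure / major region / origin / rank.

    Invariants: rostro-caudal ranks are unique within a map, and every
    structure belongs to exactly one major region.
    """

    def __init__(self, entries: Iterable[OntologyEntry]):
        self._entries: Dict[str, OntologyEntry] = {}
        structure_major: Dict[str, str] = {}
        ranks = set()
        for e in entries:
            if e.substructure in self._entries:
                raise ValueError(f"duplicate substructure code {e.substructure!r}")
            if e.rostro_caudal_rank in ranks:
                raise ValueError(
                    f"duplicate rostro-caudal rank {e.rostro_caudal_rank} "
                    f"at {e.substructure!r}"
                )
            prev = structure_major.get(e.structure)
            if prev is not None and prev != e.major_region:
                raise ValueError(
                    f"structure {e.structure!r} maps to two major regions: "
                    f"{prev!r} and {e.major_region!r}"
                )
            structure_major[e.structure] = e.major_region
            ranks.add(e.rostro_caudal_rank)
            self._entries[e.substructure] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __getitem__(self, code: str) -> OntologyEntry:
        try:
            return self._entries[code]
        except KeyError:
            raise OntologyError(f"unknown substructure code {code!r}") from None

    @property
    def substructures(self) -> List[str]:
        """Substructure codes in rostro-caudal order."""
        return sorted(self._entries, key=lambda c: self._entries[c].rostro_caudal_rank)

    def structures(self) -> List[str]:
        seen: Dict[str, None] = {}
        for code in self.substructures:
            seen.setdefault(self._entries[code].structure)
        return list(seen)

    def of_structure(self, structure: str) -> List[str]:
        return [c for c in self.substructures if self._entries[c].structure == structure]

    def of_major_region(self, major: str) -> List[str]:
        return [
            c for c in self.substructures if self._entries[c].major_region == major
        ]

    def non_white_matter(self) -> List[str]:
        return [c for c in self.substructures if not self._entries[c].white_matter]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "entries": {
                code: {
                    "structure": e.structure,
                    "major_region": e.major_region,
                    "ontogenic_origin": e.ontogenic_origin,
                    "rostro_caudal_rank": e.rostro_caudal_rank,
                    "white_matter": e.white_matter,
                }
                for code, e in self._entries.items()
            }
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "OntologyMap":
        return cls(
            OntologyEntry(
                substructure=code,
                structure=rec["structure"],
                major_region=rec["major_region"],
                ontogenic_origin=rec["ontogenic_origin"],
                rostro_caudal_rank=int(rec["rostro_caudal_rank"]),
                white_matter=bool(rec.get("white_matter", False)),
            )
            for code, rec in payload["entries"].items()
        )

    @classmethod
    def from_json(cls, path) -> "OntologyMap":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


_DEFAULT: Optional[OntologyMap] = None


def default_ontology() -> OntologyMap:
    """The packaged 111-substructure brain ontology."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("pentalayout.data").joinpath("ontology.json").read_text()
        _DEFAULT = OntologyMap.from_dict(json.loads(text))
    return _DEFAULT
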