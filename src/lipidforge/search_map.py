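"""m/z search over a generated library and identifier mapping between compound sets.

The search index is a sorted array of (theoretical m/z, record, adduct)
tuples queried by binary search — deterministic and adequate up to millions
of rows.  Identifier mapping is exact key equality on InChIKey, canonical
abbreviation or formula, reporting one row per (source, target) pair with the
per-source ambiguity count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .chem_core import ADDUCTS, AdductSpec, normalize_adduct_label

__all__ = [
    "MzQuery",
    "MzHit",
    "MzIndex",
    "mz_search",
    "MappingRow",
    "map_identifiers",
]


@dataclass(frozen=True)
class MzQuery:
    """One observed peak: m/z, tolerance (ppm or Da) and polarity."""

    mz: float
    tolerance: float
    unit: str = "ppm"  # "ppm" | "Da"
    polarity: str = "both"  # "positive" | "negative" | "both"
    adduct_filter: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError(f"tolerance must be > 0, got {self.tolerance}")
        if self.unit not in ("ppm", "Da"):
            raise ValueError(f"tolerance unit must be 'ppm' or 'Da', got {self.unit!r}")
        if self.polarity not in ("positive", "negative", "both"):
            raise ValueError(f"polarity must be positive|negative|both, got {self.polarity!r}")

    @property
    def window_da(self) -> float:
        return self.tolerance * self.mz * 1e-6 if self.unit == "ppm" else self.tolerance


@dataclass(frozen=True)
class MzHit:
    record_id: str
    adduct: str
    theoretical_mz: float
    ppm_error: float
    mass: float  # neutral monoisotopic mass, ranking tie-break

    @property
    def sort_key(self) -> tuple:
        return (abs(self.ppm_error), self.mass, self.record_id)


def _adduct_polarity(label: str, registry: Mapping[str, AdductSpec]) -> str:
    return registry[label].polarity


class MzIndex:
    """Sorted-array m/z index over library records.

    Accepts any iterable of objects exposing ``id``, ``monoisotopic_mass``
    and an ``adduct_mz`` mapping (e.g. :class:`~lipidforge.libgen.LipidRecord`).
    """

    def __init__(
        self,
        records: Iterable,
        registry: Mapping[str, AdductSpec] = ADDUCTS,
    ):
        self.registry = registry
        ids: list[str] = []
        adducts: list[str] = []
        mzs: list[float] = []
        masses: list[float] = []
        for rec in records:
            if not rec.adduct_mz:
                continue
            for label, mz in rec.adduct_mz.items():
                ids.append(rec.id)
                adducts.append(normalize_adduct_label(label))
                mzs.append(mz)
                masses.append(rec.monoisotopic_mass)
        order = np.lexsort((np.asarray(ids), np.asarray(mzs)))
        self._mz = np.asarray(mzs, dtype=float)[order]
        self._ids = np.asarray(ids, dtype=object)[order]
        self._adducts = np.asarray(adducts, dtype=object)[order]
        self._mass = np.asarray(masses, dtype=float)[order]

    def __len__(self) -> int:
        return len(self._mz)

    def search(self, query: MzQuery) -> list[MzHit]:
        """All (record, adduct) pairs within tolerance/polarity, ranked by |ppm error|."""
        w = query.window_da
        lo = int(np.searchsorted(self._mz, query.mz - w, side="left"))
        hi = int(np.searchsorted(self._mz, query.mz + w, side="right"))
        hits = []
        for i in range(lo, hi):
            label = self._adducts[i]
            if query.polarity != "both" and _adduct_polarity(label, self.registry) != query.polarity:
                continue
            if query.adduct_filter is not None and label not in query.adduct_filter:
                continue
            theo = float(self._mz[i])
            ppm = (query.mz - theo) / theo * 1e6
            hits.append(MzHit(str(self._ids[i]), str(label), theo, ppm, float(self._mass[i])))
        hits.sort(key=lambda h: h.sort_key)
        return hits


def mz_search(library: Iterable | MzIndex, query: MzQuery) -> list[MzHit]:
    """Search *library* (records or a prebuilt :class:`MzIndex`) for one peak."""
    index = library if isinstance(library, MzIndex) else MzIndex(library)
    return index.search(query)


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MappingRow:
    source_id: str
    target_id: str
    match_key: str  # "inchikey" | "abbreviation" | "formula"
    ambiguity_count: int


def _key_of(rec, key_kind: str, first_block: bool) -> Optional[str]:
    if isinstance(rec, Mapping):
        value = rec.get(key_kind)
    else:
        value = getattr(rec, key_kind, None) or None
        if value is None and key_kind == "formula":
            value = getattr(rec, "formula", None)
    if not value:
        return None
    value = str(value)
    if key_kind == "inchikey" and first_block:
        value = value.split("-")[0]
    return value


def _rec_id(rec) -> str:
    return str(rec["id"] if isinstance(rec, Mapping) else rec.id)


def map_identifiers(
    set_a: Sequence,
    set_b: Sequence,
    key_kind: str = "inchikey",
    first_block: bool = False,
) -> tuple[list[MappingRow], list[str]]:
    """Exact-key mapping from *set_a* to *set_b*.

    Records may be mappings or objects with ``id`` and the key attribute
    (``inchikey``, ``abbreviation`` or ``formula``).  ``first_block`` relaxes
    InChIKey comparison to the 14-character connectivity block.  Returns
    (rows, unmatched_source_ids); mapping is symmetric — swapping the sets
    transposes the rows.
    """
    if key_kind not in ("inchikey", "abbreviation", "formula"):
        raise ValueError(f"unsupported key kind {key_kind!r}")

    def keyed(records, label):
        out = []
        any_key = False
        for rec in records:
            k = _key_of(rec, key_kind, first_block)
            out.append((_rec_id(rec), k))
            any_key = any_key or k is not None
        if records and not any_key:
            raise ValueError(f"no record in {label} exposes key {key_kind!r}")
        return out

    a = keyed(set_a, "source set")
    b = keyed(set_b, "target set")
    targets_by_key: dict[str, list[str]] = {}
    for tid, k in b:
        if k is not None:
            targets_by_key.setdefault(k, []).append(tid)
    rows: list[MappingRow] = []
    unmatched: list[str] = []
    for sid, k in a:
        matches = targets_by_key.get(k, []) if k is not None else []
        if not matches:
            unmatched.append(sid)
            continue
        for tid in sorted(matches):
            rows.append(MappingRow(sid, tid, key_kind, len(matches)))
    return rows, unmatched
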