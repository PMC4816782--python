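"""Tracer-atlas fixtures: false-connection tables and region-name mapping.

The packaged fixtures encode the fragments of the macaque visual-cortex
tracer ground truth that are pinned down in print:

* ``fn_table`` — connections present in the classical tracer atlas but never
  found by tractography in any hemisphere (apparent false negatives), with a
  flag for the 20 that the atlas establishes with high confidence and the
  status each received in the later quantitative retrograde-tracer study
  (strong / weak / absent / untested);
* ``fp_table`` — connections found by tractography in every hemisphere but
  absent from the atlas (apparent false positives), annotated the same way;
* ``region_list`` — the 22-region visual-cortex parcellation vocabulary;
* ``region_map`` — the correspondence from these region names to the
  quantitative study's naming scheme (one region has no analogue and maps to
  nothing; two map onto the same target; two map onto combined name sets).

The tables use the name ``MSTi`` as printed; it is recorded as an alias of
``MSTl`` without resolving the discrepancy.  The full ternary ground-truth
matrix is published only as a figure raster, so anything beyond these pinned
fragments must be supplied by the user as a CSV
(:meth:`tractvalid.validation.TernaryTruth.from_csv`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "AnnotatedConnection",
    "RegionMap",
    "FixtureError",
    "load_fixture",
    "tally",
    "REGION_COUNT",
]

REGION_COUNT = 22
_MARKOV_STATUSES = {"strong", "weak", "absent", "untested"}
_LISTS = {"apparent_fn", "apparent_fp"}


class FixtureError(ValueError):
    """A packaged or user fixture violates its schema."""


@dataclass(frozen=True)
class AnnotatedConnection:
    """One unordered region pair from the false-connection tables."""

    region_a: str
    region_b: str
    list_membership: str   # apparent_fn | apparent_fp
    confident: bool        # printed in bold (clearly established in the atlas)
    markov_status: str     # strong | weak | absent | untested

    @property
    def pair(self) -> frozenset:
        return frozenset((self.region_a, self.region_b))


@dataclass(frozen=True)
class RegionMap:
    """FVE-scheme region name -> Markov-scheme name set (or None)."""

    pairs: tuple[tuple[str, frozenset | None], ...]

    def lookup(self, fve_name: str) -> frozenset | None:
        for name, target in self.pairs:
            if name == fve_name:
                return target
        raise KeyError(fve_name)

    def __len__(self) -> int:
        return len(self.pairs)


def _read(name: str) -> pd.DataFrame:
    with resources.files("tractvalid.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, keep_default_na=False)


def _vocabulary() -> tuple[list[str], dict[str, str]]:
    names = _read("region_list.csv")["name"].tolist()
    aliases = dict(zip(*(_read("region_aliases.csv")[c] for c in ("alias", "refers_to"))))
    return names, aliases


def load_fixture(name: str):
    """Load and invariant-check a packaged fixture.

    ``name`` is one of ``fn_table``, ``fp_table`` (lists of
    :class:`AnnotatedConnection`), ``region_map`` (:class:`RegionMap`), or
    ``region_list`` (list of 22 region names).
    """
    vocab, aliases = _vocabulary()
    allowed = set(vocab) | set(aliases)
    if name == "region_list":
        if len(vocab) != REGION_COUNT or len(set(vocab)) != REGION_COUNT:
            raise FixtureError("region list must contain 22 unique names")
        return vocab
    if name in ("fn_table", "fp_table"):
        df = _read(f"{name}.csv")
        expected_list = "apparent_fn" if name == "fn_table" else "apparent_fp"
        rows = []
        seen: set[frozenset] = set()
        for _, row in df.iterrows():
            conn = AnnotatedConnection(
                str(row["region_a"]), str(row["region_b"]), str(row["list"]),
                str(row["confident"]).lower() == "true", str(row["markov_status"]),
            )
            bad = (
                conn.region_a not in allowed or conn.region_b not in allowed
                or conn.list_membership != expected_list
                or conn.list_membership not in _LISTS
                or conn.markov_status not in _MARKOV_STATUSES
                or conn.region_a == conn.region_b
                or conn.pair in seen
            )
            if bad:
                raise FixtureError(f"malformed fixture row in {name}: {row.to_dict()}")
            seen.add(conn.pair)
            rows.append(conn)
        return rows
    if name == "region_map":
        df = _read("region_map.csv")
        pairs = []
        seen_names = []
        for _, row in df.iterrows():
            fve = str(row["fve_name"])
            raw = str(row["markov_names"])
            if fve not in vocab:
                raise FixtureError(f"malformed fixture row in region_map: {row.to_dict()}")
            target = frozenset(raw.split("|")) if raw else None
            pairs.append((fve, target))
            seen_names.append(fve)
        if sorted(seen_names) != sorted(vocab):
            raise FixtureError("region_map must list every FVE region exactly once")
        rm = RegionMap(tuple(pairs))
        if rm.lookup("VOT") is not None:
            raise FixtureError("VOT has no analogue and must map to nothing")
        return rm
    raise ValueError(f"unknown fixture {name!r}")


_PREDICATES = {
    "total": lambda c: True,
    "confident": lambda c: c.confident,
    "markov_tested": lambda c: c.markov_status != "untested",
    "markov_confirmed_present": lambda c: c.markov_status in ("strong", "weak"),
    "markov_confirmed_absent": lambda c: c.markov_status == "absent",
}


def tally(fixture: list[AnnotatedConnection], predicate: str) -> int:
    """Count fixture entries satisfying a predicate (see ``_PREDICATES``)."""
    if predicate not in _PREDICATES:
        raise ValueError(f"unknown predicate {predicate!r}")
    return sum(1 for c in fixture if _PREDICATES[predicate](c))
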