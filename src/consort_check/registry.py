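"""Machine-readable registry of the 37 CONSORT 2010 checklist sub-items.

The CONSORT 2010 statement enumerates 25 numbered items, several of which are
split into lettered sub-items, for a total of 37.  Each registry record carries
the checklist prompt, the manuscript region it is expected in, and two flags
that drive the rest of the pipeline:

* ``status`` — three sub-items (2a, 22, 17b) are too subjective for rule-based
  detection and are carried as ``not_implemented``;
* ``in_accuracy`` — item 10 (best-effort only) and the figure/table items
  13a, 13b, 16 are additionally excluded from accuracy scoring, leaving 30
  scored items.

The registry itself is a tab-separated resource shipped with the package so it
can be reviewed and amended without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterator

__all__ = [
    "ChecklistItem",
    "Registry",
    "RegistryError",
    "load_registry",
    "lookup_item",
    "NOT_IMPLEMENTED_ITEMS",
    "FIGURE_CHECK_ITEMS",
    "SCORING_EXCLUDED_ITEMS",
    "CONSORT_ORDER",
]

#: Sub-items deliberately left undetected (subjective / recommendation only).
NOT_IMPLEMENTED_ITEMS = frozenset({"2a", "22", "17b"})

#: Participant-flow items whose evidence may live inside a figure or table.
FIGURE_CHECK_ITEMS = frozenset({"13a", "13b", "16"})

#: Everything excluded from accuracy: the three above plus best-effort item 10.
SCORING_EXCLUDED_ITEMS = NOT_IMPLEMENTED_ITEMS | FIGURE_CHECK_ITEMS | {"10"}

#: Canonical CONSORT 2010 ordering of the 37 sub-item codes.
CONSORT_ORDER = (
    "1a", "1b", "2a", "2b", "3a", "3b", "4a", "4b", "5", "6a", "6b",
    "7a", "7b", "8a", "8b", "9", "10", "11a", "11b", "12a", "12b",
    "13a", "13b", "14a", "14b", "15", "16", "17a", "17b", "18", "19",
    "20", "21", "22", "23", "24", "25",
)

VALID_SECTIONS = frozenset(
    {"INTRODUCTION", "METHODS", "RESULTS", "DISCUSSION", "OTHER_INFO"}
)
VALID_SCOPES = frozenset({"TITLE", "ABSTRACT", "BODY"})

_RESOURCE = "checklist_items.tsv"


class RegistryError(Exception):
    """Raised when the packaged registry resource is missing or corrupt."""


@dataclass(frozen=True)
class ChecklistItem:
    """One CONSORT 2010 checklist sub-item."""

    item_id: str
    prompt: str
    scope: str  # TITLE | ABSTRACT | BODY
    expected_sections: frozenset[str] = field(default_factory=frozenset)
    status: str = "detectable"  # detectable | not_implemented
    in_accuracy: bool = True
    figure_check: bool = False

    def __post_init__(self) -> None:
        if self.scope not in VALID_SCOPES:
            raise RegistryError(f"item {self.item_id}: bad scope {self.scope!r}")
        bad = self.expected_sections - VALID_SECTIONS
        if bad:
            raise RegistryError(f"item {self.item_id}: bad sections {sorted(bad)}")


class Registry:
    """Ordered, immutable collection of the 37 checklist sub-items."""

    def __init__(self, items: list[ChecklistItem]):
        self._items = tuple(items)
        self._by_id = {it.item_id: it for it in items}
        self._validate()

    def _validate(self) -> None:
        ids = [it.item_id for it in self._items]
        if len(ids) != len(set(ids)):
            raise RegistryError("duplicate item ids in registry")
        if tuple(ids) != CONSORT_ORDER:
            raise RegistryError(
                "registry must contain exactly the 37 CONSORT 2010 sub-items "
                "in checklist order"
            )
        not_impl = {it.item_id for it in self._items if it.status == "not_implemented"}
        if not_impl != NOT_IMPLEMENTED_ITEMS:
            raise RegistryError(f"not_implemented set is {sorted(not_impl)}")
        excluded = {it.item_id for it in self._items if not it.in_accuracy}
        if excluded != SCORING_EXCLUDED_ITEMS:
            raise RegistryError(f"accuracy-excluded set is {sorted(excluded)}")
        figs = {it.item_id for it in self._items if it.figure_check}
        if figs != FIGURE_CHECK_ITEMS:
            raise RegistryError(f"figure_check set is {sorted(figs)}")

    def __iter__(self) -> Iterator[ChecklistItem]:
        return iter(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Registry) and self._items == other._items

    def __getitem__(self, item_id: str) -> ChecklistItem:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise KeyError(f"unknown CONSORT item id: {item_id!r}") from None

    @property
    def items(self) -> tuple[ChecklistItem, ...]:
        return self._items

    def scored_items(self) -> tuple[ChecklistItem, ...]:
        """The 30 sub-items that participate in accuracy scoring."""
        return tuple(it for it in self._items if it.in_accuracy)


def _parse_row(line: str, lineno: int) -> ChecklistItem:
    cols = line.split("\t")
    if len(cols) != 7:
        raise RegistryError(f"{_RESOURCE}:{lineno}: expected 7 columns, got {len(cols)}")
    item_id, scope, sections, status, in_acc, fig, prompt = cols
    if status not in ("detectable", "not_implemented"):
        raise RegistryError(f"{_RESOURCE}:{lineno}: bad status {status!r}")
    expected = frozenset() if sections == "-" else frozenset(sections.split(","))
    return ChecklistItem(
        item_id=item_id,
        prompt=prompt,
        scope=scope,
        expected_sections=expected,
        status=status,
        in_accuracy=in_acc == "1",
        figure_check=fig == "1",
    )


def load_registry() -> Registry:
    """Load the packaged registry of all 37 checklist sub-items.

    Pure: repeated loads compare equal element-wise (the parsed registry is
    cached; items are immutable).

    Raises
    ------
    RegistryError
        If the packaged resource is absent or fails its invariants.
    """
    return _load_registry_cached()


@lru_cache(maxsize=1)
def _load_registry_cached() -> Registry:
    try:
        text = (
            resources.files("consort_check.data").joinpath(_RESOURCE).read_text("utf-8")
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise RegistryError(f"registry resource {_RESOURCE!r} not found") from exc
    items = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        items.append(_parse_row(line, lineno))
    return Registry(items)


def lookup_item(item_id: str, registry: Registry | None = None) -> ChecklistItem:
    """Return the unique checklist sub-item with the given id.

    Raises ``KeyError`` (echoing the id) for ids outside the registry.
    """
    reg = registry if registry is not None else load_registry()
    return reg[item_id]
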