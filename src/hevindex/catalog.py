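"""Hierarchical indicator catalogs.

A catalog is a three-layer tree — pillar, indicator, sub-indicator — that
drives all scoring.  The three pillars follow the IPCC AR5 risk algebra:
hazard, exposure and vulnerability, with potential impact their
non-compensable product.  Vulnerability indicators additionally carry a
component tag (sensitivity, coping capacity or adaptive capacity; the
capacities are encoded as *lacks*, so that a higher raw value is always
worse).

Catalogs are plain YAML mappings so public-health users can hand-edit them;
:func:`load_catalog` validates every structural invariant and reports *all*
violations, not just the first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

LAYERS = ("pillar", "indicator", "sub-indicator")
PILLARS = ("hazard", "exposure", "vulnerability")
COMPONENTS = ("sensitivity", "coping", "adaptive")

#: schema version written to / expected in catalog files
SCHEMA_VERSION = 1


class CatalogError(ValueError):
    """Raised when a catalog file cannot be parsed into nodes."""


class CatalogValidationError(CatalogError):
    """Raised when a parsed catalog violates structural invariants.

    Carries the full issue list so a user can fix everything in one pass.
    """

    def __init__(self, issues: list["Issue"]):
        self.issues = list(issues)
        lines = "; ".join(str(i) for i in self.issues)
        super().__init__(f"invalid catalog ({len(self.issues)} issue(s)): {lines}")


@dataclass(frozen=True)
class Issue:
    """One validation finding: the node it concerns and the rule violated."""

    node_id: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.node_id}] {self.rule}: {self.message}"


@dataclass(frozen=True)
class IndicatorNode:
    """One node of the indicator tree.

    ``target`` is the positive reference value used for distance-to-target
    normalization and is meaningful for sub-indicators only.  ``weight`` is
    a non-negative relative weight within the node's sibling group.
    ``polarity`` asserts "higher raw value = worse"; capacity indicators are
    phrased as lacks so this holds throughout the shipped catalog.
    """

    id: str
    label: str
    layer: str
    parent: str = ""
    pillar: str = ""
    component: str = ""
    target: float | None = None
    weight: float = 1.0
    polarity: bool = True


@dataclass(frozen=True)
class IndicatorCatalog:
    """A validated indicator tree plus scoring metadata.

    ``scales`` holds the per-pillar scale constants divided out at the
    pillar layer (see :func:`hevindex.scoring.score_pillar`).
    """

    nodes: tuple[IndicatorNode, ...]
    name: str = "catalog"
    version: str = "0"
    scales: Mapping[str, float] = field(
        default_factory=lambda: {"hazard": 1.0, "exposure": 1.0, "vulnerability": 1.0}
    )

    # -- lookup helpers ------------------------------------------------
    def node(self, node_id: str) -> IndicatorNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise KeyError(f"unknown catalog node {node_id!r}") from None

    @property
    def _by_id(self) -> dict[str, IndicatorNode]:
        cached = object.__getattribute__(self, "__dict__").get("_by_id_cache")
        if cached is None:
            cached = {n.id: n for n in self.nodes}
            object.__getattribute__(self, "__dict__")["_by_id_cache"] = cached
        return cached

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._by_id

    def by_layer(self, layer: str) -> tuple[IndicatorNode, ...]:
        return tuple(n for n in self.nodes if n.layer == layer)

    def children(self, node_id: str) -> tuple[IndicatorNode, ...]:
        return tuple(n for n in self.nodes if n.parent == node_id)

    def indicators(self, pillar: str) -> tuple[IndicatorNode, ...]:
        return tuple(
            n for n in self.nodes if n.layer == "indicator" and n.pillar == pillar
        )

    def sub_indicators(self, indicator_id: str | None = None) -> tuple[IndicatorNode, ...]:
        subs = self.by_layer("sub-indicator")
        if indicator_id is None:
            return subs
        return tuple(n for n in subs if n.parent == indicator_id)

    def sub_indicator_ids(self, pillar: str | None = None) -> tuple[str, ...]:
        return tuple(
            n.id
            for n in self.by_layer("sub-indicator")
            if pillar is None or n.pillar == pillar
        )

    def scale(self, pillar: str) -> float:
        return float(self.scales.get(pillar, 1.0))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_catalog(catalog: IndicatorCatalog) -> list[Issue]:
    """Check every structural invariant; return a (possibly empty) issue list.

    The report is exhaustive: one entry per violated rule per node.
    """
    issues: list[Issue] = []
    seen: dict[str, int] = {}
    for n in catalog.nodes:
        seen[n.id] = seen.get(n.id, 0) + 1
    for node_id, count in seen.items():
        if count > 1:
            issues.append(Issue(node_id, "unique-id", f"id appears {count} times"))

    by_id = {n.id: n for n in catalog.nodes}
    pillar_nodes = [n for n in catalog.nodes if n.layer == "pillar"]
    pillar_ids = sorted(n.pillar for n in pillar_nodes)
    if pillar_ids != sorted(PILLARS):
        issues.append(
            Issue(
                "<catalog>",
                "three-pillars",
                f"expected exactly one pillar node per {PILLARS}, got {pillar_ids}",
            )
        )

    layer_above = {"sub-indicator": "indicator", "indicator": "pillar"}
    for n in catalog.nodes:
        if n.layer not in LAYERS:
            issues.append(Issue(n.id, "layer", f"unknown layer {n.layer!r}"))
            continue
        if n.pillar not in PILLARS:
            issues.append(Issue(n.id, "pillar", f"unknown pillar {n.pillar!r}"))
        if n.layer == "pillar":
            if n.parent:
                issues.append(Issue(n.id, "root", "pillar node must have no parent"))
        else:
            parent = by_id.get(n.parent)
            if parent is None:
                issues.append(Issue(n.id, "parent", f"parent {n.parent!r} not found"))
            else:
                if parent.layer != layer_above[n.layer]:
                    issues.append(
                        Issue(
                            n.id,
                            "layering",
                            f"parent {parent.id} is a {parent.layer}, "
                            f"expected {layer_above[n.layer]}",
                        )
                    )
                if parent.pillar != n.pillar:
                    issues.append(
                        Issue(n.id, "pillar-consistency",
                              f"pillar {n.pillar!r} != parent pillar {parent.pillar!r}")
                    )
        if n.component:
            if n.pillar != "vulnerability":
                issues.append(
                    Issue(n.id, "component", "component tag only valid under vulnerability")
                )
            elif n.component not in COMPONENTS:
                issues.append(Issue(n.id, "component", f"unknown component {n.component!r}"))
        if n.layer == "sub-indicator":
            if n.target is None or not (n.target > 0):
                issues.append(Issue(n.id, "target", f"target must be > 0, got {n.target}"))
        if n.weight < 0:
            issues.append(Issue(n.id, "weight", f"weight must be >= 0, got {n.weight}"))

    # every sibling group needs at least one positive weight
    parents = {n.parent for n in catalog.nodes if n.parent}
    for pid in sorted(parents):
        sibs = [n for n in catalog.nodes if n.parent == pid]
        if sibs and not any(s.weight > 0 for s in sibs):
            issues.append(
                Issue(pid, "sibling-weights", "all child weights are zero")
            )
    return issues


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_NODE_KEYS = {f.name for f in dataclasses.fields(IndicatorNode)}


def _node_from_mapping(raw: Mapping, index: int) -> IndicatorNode:
    if not isinstance(raw, Mapping):
        raise CatalogError(f"node #{index}: expected a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _NODE_KEYS
    if unknown:
        raise CatalogError(f"node #{index}: unknown key(s) {sorted(unknown)}")
    if "id" not in raw or "layer" not in raw:
        raise CatalogError(f"node #{index}: missing required key 'id' or 'layer'")
    kwargs = dict(raw)
    kwargs.setdefault("label", kwargs["id"])
    if kwargs.get("target") is not None:
        try:
            kwargs["target"] = float(kwargs["target"])
        except (TypeError, ValueError):
            raise CatalogError(
                f"node #{index} ({raw['id']}): key 'target' is not numeric"
            ) from None
    if "weight" in kwargs and kwargs["weight"] is not None:
        try:
            kwargs["weight"] = float(kwargs["weight"])
        except (TypeError, ValueError):
            raise CatalogError(
                f"node #{index} ({raw['id']}): key 'weight' is not numeric"
            ) from None
    return IndicatorNode(**{k: v for k, v in kwargs.items() if v is not None or k == "target"})


def load_catalog(path: str | Path) -> IndicatorCatalog:
    """Load and validate a catalog file.

    Raises :class:`CatalogError` on schema problems (naming the offending
    key) and :class:`CatalogValidationError` listing *all* invariant
    violations otherwise.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _catalog_from_document(doc)


def _catalog_from_document(doc) -> IndicatorCatalog:
    if not isinstance(doc, Mapping):
        raise CatalogError("catalog file must be a mapping at top level")
    if doc.get("schema") != SCHEMA_VERSION:
        raise CatalogError(
            f"key 'schema': expected {SCHEMA_VERSION}, got {doc.get('schema')!r}"
        )
    raw_nodes = doc.get("nodes")
    if not isinstance(raw_nodes, list) or not raw_nodes:
        raise CatalogError("key 'nodes': expected a non-empty list")
    nodes = tuple(_node_from_mapping(raw, i) for i, raw in enumerate(raw_nodes))
    scales = doc.get("scales") or {}
    if not isinstance(scales, Mapping):
        raise CatalogError("key 'scales': expected a mapping pillar -> positive number")
    for k, v in scales.items():
        if k not in PILLARS or not isinstance(v, (int, float)) or v <= 0:
            raise CatalogError(f"key 'scales.{k}': expected a positive number per pillar")
    catalog = IndicatorCatalog(
        nodes=nodes,
        name=str(doc.get("name", "catalog")),
        version=str(doc.get("version", "0")),
        scales={p: float(scales.get(p, 1.0)) for p in PILLARS},
    )
    issues = validate_catalog(catalog)
    if issues:
        raise CatalogValidationError(issues)
    return catalog


def write_catalog(catalog: IndicatorCatalog, path: str | Path) -> None:
    """Write a catalog back to YAML; ``load_catalog`` round-trips it exactly."""
    doc = {
        "schema": SCHEMA_VERSION,
        "name": catalog.name,
        "version": catalog.version,
        "scales": {k: float(v) for k, v in catalog.scales.items()},
        "nodes": [
            {
                k: v
                for k, v in dataclasses.asdict(n).items()
                if not (k == "target" and v is None)
                and not (k == "component" and v == "")
                and not (k == "parent" and v == "")
            }
            for n in catalog.nodes
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


_KHON_KAEN_CACHE: IndicatorCatalog | None = None


def khon_kaen_catalog() -> IndicatorCatalog:
    """The built-in Khon Kaen city catalog.

    3 hazard, 2 exposure and 17 vulnerability indicators; 9 sensitivity
    sub-indicators under V1-V5 and 40 capacity sub-indicators under
    V6-V17.  Sub-indicators not individually named in the source material
    are neutral placeholder slots (V6.1, V6.2, ...) honouring the published
    counts.
    """
    global _KHON_KAEN_CACHE
    if _KHON_KAEN_CACHE is None:
        ref = resources.files("hevindex").joinpath("data/khon_kaen_catalog.yaml")
        with resources.as_file(ref) as p:
            _KHON_KAEN_CACHE = load_catalog(p)
    return _KHON_KAEN_CACHE
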