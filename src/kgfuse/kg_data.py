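"""Knowledge-graph I/O, schema reduction, drug-disease splitting and candidate
enumeration.

A knowledge graph here is a set of directed ``(head, relation, tail)`` triples
over entities typed as ``drug``, ``protein`` or ``disease``. The link-prediction
task targets the drug->disease relation, so splitting is asymmetric: validation
and test contain *only* drug-disease triples while the training split keeps
every edge type. The candidate space for prediction is the cross product of
drugs and diseases (by default those appearing in the test split) minus any
pair already asserted in train or validation.

File formats are plain TSV: triple files are ``head\\trelation\\ttail`` with no
header (a header row can be tolerated via a flag), and entity types come in a
separate two-column ``entity\\ttype`` file because neither common triple-file
dialect encodes types. Identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError, EntityTypingError, TripleParseError

logger = logging.getLogger(__name__)

DRUG = "drug"
PROTEIN = "protein"
DISEASE = "disease"
CORE_TYPES = frozenset({DRUG, PROTEIN, DISEASE})


class Triple(NamedTuple):
    """A directed (head, relation, tail) assertion.

    Triples are directed: ``(h, r, t)`` and ``(t, r, h)`` are distinct, and no
    inverse triples are ever added implicitly.
    """

    head: str
    relation: str
    tail: str


@dataclass
class KnowledgeGraph:
    """A set of triples plus an entity -> type map covering every entity used."""

    triples: set[Triple]
    entity_types: dict[str, str]

    def __post_init__(self) -> None:
        missing = sorted(
            {e for t in self.triples for e in (t.head, t.tail)}
            - self.entity_types.keys()
        )
        if missing:
            raise EntityTypingError(
                f"{len(missing)} entities have no type: {missing[:10]}"
            )

    def entities_of_type(self, etype: str) -> set[str]:
        return {e for e, ty in self.entity_types.items() if ty == etype}

    def drug_disease_triples(self) -> set[Triple]:
        """Triples whose head is a drug and whose tail is a disease."""
        et = self.entity_types
        return {
            t
            for t in self.triples
            if et[t.head] == DRUG and et[t.tail] == DISEASE
        }

    def degree(self) -> dict[str, int]:
        """Undirected degree (in + out) of every typed entity."""
        deg = {e: 0 for e in self.entity_types}
        for t in self.triples:
            deg[t.head] += 1
            deg[t.tail] += 1
        return deg

    def __len__(self) -> int:
        return len(self.triples)


@dataclass
class SplitBundle:
    """Disjoint train/validation/test triple sets.

    Validation and test hold exclusively drug->disease triples; every other
    edge type lives in train.
    """

    train: set[Triple]
    validation: set[Triple]
    test: set[Triple]
    ratios: tuple[float, float, float]
    seed: int
    entity_types: dict[str, str] = field(default_factory=dict)

    def splits(self) -> dict[str, set[Triple]]:
        return {"train": self.train, "validation": self.validation, "test": self.test}

    def test_pairs(self) -> set[tuple[str, str]]:
        return {(t.head, t.tail) for t in self.test}


@dataclass
class CandidateSpace:
    """Drug x disease pairs eligible for prediction, in deterministic order."""

    pairs: list[tuple[str, str]]
    scope: str

    def __post_init__(self) -> None:
        self.pairs = sorted(set(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)


def read_triples(
    path: str | Path,
    type_map_path: str | Path,
    *,
    header: bool = False,
) -> KnowledgeGraph:
    """Read a TSV triple file plus a two-column entity-type TSV.

    Lines with fewer than three columns raise :class:`TripleParseError` naming
    the offending line number; extra columns beyond the third are ignored.
    Duplicate triples are dropped with a logged count. Every entity must be
    covered by the type map or :class:`EntityTypingError` is raised.
    """
    path = Path(path)
    triples: set[Triple] = set()
    n_lines = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if header and lineno == 1:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) < 3:
                raise TripleParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, "
                    f"got {len(row)}"
                )
            h, r, t = row[0].strip(), row[1].strip(), row[2].strip()
            if not h or not t:
                raise TripleParseError(
                    f"{path}: line {lineno}: empty head or tail identifier"
                )
            n_lines += 1
            triples.add(Triple(h, r, t))
    n_dup = n_lines - len(triples)
    if n_dup:
        logger.info("read_triples(%s): dropped %d duplicate triples", path, n_dup)
    entity_types = read_type_map(type_map_path)
    used = {e for t in triples for e in (t.head, t.tail)}
    missing = used - entity_types.keys()
    if missing:
        raise EntityTypingError(
            f"{len(missing)} entities missing from type map: {sorted(missing)[:10]}"
        )
    return KnowledgeGraph(triples, {e: entity_types[e] for e in used})


def read_type_map(path: str | Path) -> dict[str, str]:
    """Read an ``entity\\ttype`` TSV into a dict."""
    path = Path(path)
    out: dict[str, str] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise TripleParseError(
                    f"{path}: line {lineno}: expected 2 columns (entity, type)"
                )
            out[row[0].strip()] = row[1].strip()
    return out


def write_triples(triples: Iterable[Triple], path: str | Path) -> None:
    """Write triples as head\\trelation\\ttail TSV, sorted for determinism."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for t in sorted(triples):
            writer.writerow(t)


def write_type_map(entity_types: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for e in sorted(entity_types):
            writer.writerow([e, entity_types[e]])


def reduce_schema(
    kg: KnowledgeGraph,
    keep_types: set[str] = CORE_TYPES,
    keep_relations: Optional[set[str]] = None,
) -> KnowledgeGraph:
    """Restrict a KG to triples whose endpoints are both of a kept type.

    Optionally also whitelist relation labels (e.g. retaining only causal
    protein-protein relations such as ``activates``/``inhibits``). The entity
    type map is pruned to surviving entities. Idempotent.
    """
    if not keep_types:
        raise ConfigError("keep_types must be non-empty")
    et = kg.entity_types
    kept = {
        t
        for t in kg.triples
        if et[t.head] in keep_types
        and et[t.tail] in keep_types
        and (keep_relations is None or t.relation in keep_relations)
    }
    if not kept:
        warnings.warn("reduce_schema produced an empty knowledge graph", stacklevel=2)
    surviving = {e for t in kept for e in (t.head, t.tail)}
    return KnowledgeGraph(kept, {e: et[e] for e in surviving})


def split_drug_disease(
    kg: KnowledgeGraph,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitBundle:
    """Partition drug-disease triples into train/validation/test.

    The drug-disease triples are sorted lexicographically, shuffled with a
    seeded permutation (platform-independent), and cut so that
    ``|test| = floor(N * test_frac)``, ``|validation| = floor(N * valid_frac)``
    and train receives the remainder plus every non-drug-disease triple.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigError(f"split ratios must sum to 1, got {ratios}")
    if any(r < 0 for r in ratios):
        raise ConfigError(f"split ratios must be non-negative, got {ratios}")
    dd = sorted(kg.drug_disease_triples())
    if not dd:
        raise DataError("knowledge graph contains no drug-disease triples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dd))
    shuffled = [dd[i] for i in order]
    n = len(dd)
    n_valid = math.floor(n * ratios[1])
    n_test = math.floor(n * ratios[2])
    n_train = n - n_valid - n_test
    train_dd = set(shuffled[:n_train])
    valid = set(shuffled[n_train : n_train + n_valid])
    test = set(shuffled[n_train + n_valid :])
    other = kg.triples - set(dd)
    return SplitBundle(
        train=train_dd | other,
        validation=valid,
        test=test,
        ratios=tuple(ratios),
        seed=seed,
        entity_types=dict(kg.entity_types),
    )


def enumerate_candidates(
    split: SplitBundle,
    scope: str = "test_entities",
) -> CandidateSpace:
    """Enumerate the drug x disease pairs eligible for prediction.

    With ``scope="test_entities"`` (default), the drugs and diseases are those
    appearing in the test split; with ``scope="all_entities"``, every typed
    drug and disease. Pairs already asserted as drug-disease triples in train
    or validation are excluded, so the space never contains an edge the models
    could have seen. Ordering is deterministic: sorted by (drug, disease).
    """
    if scope not in ("test_entities", "all_entities"):
        raise ConfigError(f"unknown candidate scope: {scope!r}")
    if not split.test:
        raise DataError("test split is empty; cannot enumerate candidates")
    et = split.entity_types
    if scope == "test_entities":
        drugs = sorted({t.head for t in split.test})
        diseases = sorted({t.tail for t in split.test})
    else:
        drugs = sorted(e for e, ty in et.items() if ty == DRUG)
        diseases = sorted(e for e, ty in et.items() if ty == DISEASE)
    seen = {
        (t.head, t.tail)
        for t in split.train | split.validation
        if et.get(t.head) == DRUG and et.get(t.tail) == DISEASE
    }
    pairs = [(d, z) for d in drugs for z in diseases if (d, z) not in seen]
    if not pairs:
        raise DataError("candidate space is empty after removing seen pairs")
    return CandidateSpace(pairs=pairs, scope=scope)


def save_split(split: SplitBundle, out_dir: str | Path) -> dict:
    """Serialize a SplitBundle as train/valid/test TSVs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = {"train": split.train, "valid": split.validation, "test": split.test}
    for name, triples in names.items():
        write_triples(triples, out / f"{name}.tsv")
    write_type_map(split.entity_types, out / "entity_types.tsv")
    manifest = {
        "ratios": list(split.ratios),
        "seed": split.seed,
        "counts": {k: len(v) for k, v in names.items()},
    }
    (out / "split_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def load_split(in_dir: str | Path) -> SplitBundle:
    """Inverse of :func:`save_split`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "split_manifest.json").read_text())
    entity_types = read_type_map(in_dir / "entity_types.tsv")

    def _load(name: str) -> set[Triple]:
        triples: set[Triple] = set()
        p = in_dir / f"{name}.tsv"
        with p.open(newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if row:
                    triples.add(Triple(row[0], row[1], row[2]))
        return triples

    return SplitBundle(
        train=_load("train"),
        validation=_load("valid"),
        test=_load("test"),
        ratios=tuple(manifest["ratios"]),
        seed=manifest["seed"],
        entity_types=entity_types,
    )
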