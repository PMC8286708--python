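"""Typed data model and TSV readers/writers for PharmGKB-style annotation data.

The on-disk dialect is owned by this package: tab-delimited UTF-8 tables with a
header row and no quoting (tabs may not occur inside fields).  Real PharmGKB
exports can be adapted via the ``columns`` mapping accepted by the readers.

Variant annotation tables carry one row per (rsid, gene, drug); rows sharing an
(rsid, gene) key are aggregated into a single :class:`VariantRecord`, merging
effect types for the same drug.  Evidence sub-levels such as ``1A``/``2B`` are
mapped to their major category (the leading digit), since the analysis groups
variants by major PharmGKB category 1-4 only.

Missing score values are a first-class state: empty cells and the literal token
``NA`` read as missing, and writers emit ``NA``.  Missing is never silently
coerced to zero.
"""

from __future__ import annotations

import csv
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EFFECT_TYPES",
    "TOXICITY",
    "CONSEQUENCES",
    "DEFAULT_TOOLS",
    "SchemaError",
    "RowError",
    "DrugEffect",
    "VariantRecord",
    "GeneAnnotation",
    "GeneAnnotationMap",
    "ToolScoreTable",
    "TruthLabel",
    "read_variant_annotations",
    "write_variant_annotations",
    "read_score_table",
    "write_score_table",
    "read_gene_annotations",
    "write_gene_annotations",
    "read_clinvar_set",
    "write_clinvar_set",
    "read_truth_set",
    "write_truth_set",
]

#: Effect-type vocabulary used by PharmGKB clinical annotations.
EFFECT_TYPES = frozenset({"Toxicity/ADR", "Efficacy", "Dosage", "Metabolism/PK", "Other"})

#: The effect type the Type B cascade keys on.
TOXICITY = "Toxicity/ADR"

CONSEQUENCES = ("missense", "synonymous", "noncoding")

#: The eleven functional-inference tools scored in the benchmark.
DEFAULT_TOOLS = [
    "SIFT",
    "PolyPhen2",
    "CADD",
    "DANN",
    "FATHMM",
    "GERP++",
    "MutPred",
    "MutationAssessor",
    "MutationTaster",
    "REVEL",
    "PhastCons",
]

_RSID_RE = re.compile(r"^rs[0-9]+$")
_EVIDENCE_RE = re.compile(r"^([1-4])[A-Za-z]?$")
_MISSING_TOKENS = ("", "NA")


class SchemaError(ValueError):
    """A file's header or table-level contract is violated."""


class RowError(ValueError):
    """A single row is malformed; the message carries the 1-based line number."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugEffect:
    """Annotated effect types of one variant for one drug or chemical."""

    drug: str
    effect_types: frozenset[str]

    def __post_init__(self) -> None:
        if not self.drug:
            raise ValueError("DrugEffect.drug must be non-empty")
        if not self.effect_types:
            raise ValueError(f"DrugEffect for {self.drug!r}: effect_types must be non-empty")
        unknown = set(self.effect_types) - EFFECT_TYPES
        if unknown:
            raise ValueError(f"unknown effect types {sorted(unknown)} for drug {self.drug!r}")


@dataclass(frozen=True)
class VariantRecord:
    """One pharmacogenetic variant in its gene context.

    ``evidence_category`` is the major PharmGKB confidence level (1 highest,
    4 lowest).  ``drug_effects`` may be empty for variants lacking per-drug
    clinical annotations.
    """

    rsid: str
    gene: str
    consequence: str
    evidence_category: int
    drug_effects: tuple[DrugEffect, ...] = ()

    def __post_init__(self) -> None:
        if not _RSID_RE.match(self.rsid):
            raise ValueError(f"malformed rsid {self.rsid!r} (expected rs<digits>)")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"{self.rsid}: consequence {self.consequence!r} not in {CONSEQUENCES}"
            )
        if self.evidence_category not in (1, 2, 3, 4):
            raise ValueError(f"{self.rsid}: evidence_category must be 1-4")

    @property
    def key(self) -> tuple[str, str]:
        return (self.rsid, self.gene)

    def effects_for(self, drug: str) -> frozenset[str]:
        for de in self.drug_effects:
            if de.drug == drug:
                return de.effect_types
        return frozenset()

    def has_effect_type(self, effect_type: str) -> bool:
        return any(effect_type in de.effect_types for de in self.drug_effects)


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene flags consulted by the cascade: PharmaADME membership and GO terms."""

    gene: str
    is_adme: bool = False
    go_terms: frozenset[str] = frozenset()


class GeneAnnotationMap(Mapping):
    """Case-insensitive gene-symbol lookup; unknown genes yield a default annotation."""

    def __init__(self, annotations: Iterable[GeneAnnotation] = ()) -> None:
        self._by_symbol: dict[str, GeneAnnotation] = {}
        for ann in annotations:
            self._by_symbol[ann.gene.upper()] = ann

    def __getitem__(self, gene: str) -> GeneAnnotation:
        return self._by_symbol[gene.upper()]

    def get(self, gene: str, default: GeneAnnotation | None = None) -> GeneAnnotation:
        try:
            return self[gene]
        except KeyError:
            return default if default is not None else GeneAnnotation(gene)

    def __contains__(self, gene: object) -> bool:
        return isinstance(gene, str) and gene.upper() in self._by_symbol

    def __iter__(self):
        return iter(self._by_symbol)

    def __len__(self) -> int:
        return len(self._by_symbol)


@dataclass
class ToolScoreTable:
    """Variant x tool matrix of raw functional-inference scores.

    ``scores`` is a float DataFrame indexed by unique rsid with one column per
    tool; NaN encodes a missing value.  ``groups`` labels every row with its
    evidence category ("1".."4") or "random" for the common-variant background.
    """

    tools: list[str]
    scores: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if list(self.scores.columns) != list(self.tools):
            self.scores = self.scores.reindex(columns=self.tools)
        if not self.scores.index.is_unique:
            dup = self.scores.index[self.scores.index.duplicated()][0]
            raise SchemaError(f"duplicate rsid {dup!r} in score table")
        if not self.scores.index.equals(self.groups.index):
            raise SchemaError("scores and groups must be indexed by the same rsids")

    @property
    def rsids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def values(self, tool: str, group: str | None = None) -> np.ndarray:
        """Raw scores (NaN for missing) for one tool, optionally one group."""
        if tool not in self.tools:
            raise KeyError(tool)
        col = self.scores[tool]
        if group is not None:
            if group not in set(self.groups):
                raise KeyError(group)
            col = col[self.groups == group]
        return col.to_numpy(dtype=float)

    def subset(self, rsids: Iterable[str]) -> "ToolScoreTable":
        idx = [r for r in self.scores.index if r in set(rsids)]
        return ToolScoreTable(list(self.tools), self.scores.loc[idx].copy(), self.groups.loc[idx].copy())

    def equals(self, other: "ToolScoreTable") -> bool:
        return (
            self.tools == other.tools
            and self.scores.equals(other.scores)
            and self.groups.equals(other.groups)
        )


@dataclass(frozen=True)
class TruthLabel:
    """Literature-derived Type A / Type B label for one truth-set variant."""

    rsid: str
    label: str
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("TypeA", "TypeB"):
            raise ValueError(f"{self.rsid}: label must be TypeA or TypeB, got {self.label!r}")


# ---------------------------------------------------------------------------
# variant annotation tables
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = ("rsid", "gene", "consequence", "evidence_category", "drug", "effect_types")
_EFFECT_SEP = ";"


def _open_table(path, required: tuple[str, ...], columns: Mapping[str, str] | None):
    """Yield (line_number, {canonical: value}) dicts from a TSV file."""
    colmap = {c: (columns or {}).get(c, c) for c in required}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, header required") from None
        pos = {name: i for i, name in enumerate(header)}
        for canonical, actual in colmap.items():
            if actual not in pos:
                raise SchemaError(f"{path}: missing required column {actual!r}")
        rows = []
        for lineno, raw in enumerate(reader, start=2):
            if not raw or (len(raw) == 1 and not raw[0].strip()):
                continue
            rows.append((lineno, {c: (raw[pos[colmap[c]]] if pos[colmap[c]] < len(raw) else "").strip() for c in required}))
    return rows


def _parse_evidence(token: str, lineno: int) -> int:
    m = _EVIDENCE_RE.match(token.strip())
    if not m:
        raise RowError(f"line {lineno}: evidence category {token!r} not in 1-4 (or sub-level such as 1A)")
    return int(m.group(1))


def read_variant_annotations(path, columns: Mapping[str, str] | None = None) -> list[VariantRecord]:
    """Read a variant annotation TSV into aggregated :class:`VariantRecord` s.

    Rows sharing (rsid, gene) merge into one record; effect types for the same
    drug within that key merge into one set.  Records keep first-seen file
    order.  Rows with an empty drug cell contribute no drug effect.
    """
    rows = _open_table(path, _VARIANT_COLUMNS, columns)
    order: list[tuple[str, str]] = []
    consequence: dict[tuple[str, str], str] = {}
    evidence: dict[tuple[str, str], int] = {}
    effects: dict[tuple[str, str], dict[str, set[str]]] = {}
    for lineno, row in rows:
        key = (row["rsid"], row["gene"])
        cat = _parse_evidence(row["evidence_category"], lineno)
        if key not in consequence:
            order.append(key)
            consequence[key] = row["consequence"]
            evidence[key] = cat
            effects[key] = {}
        else:
            if consequence[key] != row["consequence"]:
                raise RowError(
                    f"line {lineno}: conflicting consequence {row['consequence']!r} for {key}"
                )
            if evidence[key] != cat:
                raise RowError(f"line {lineno}: conflicting evidence category for {key}")
        if row["drug"]:
            tokens = [t.strip() for t in row["effect_types"].split(_EFFECT_SEP) if t.strip()]
            if not tokens:
                raise RowError(f"line {lineno}: drug {row['drug']!r} with no effect types")
            effects[key].setdefault(row["drug"], set()).update(tokens)
        elif row["effect_types"]:
            raise RowError(f"line {lineno}: effect types given without a drug")
    records = []
    for key in order:
        try:
            des = tuple(
                DrugEffect(drug, frozenset(ets)) for drug, ets in effects[key].items()
            )
            records.append(
                VariantRecord(key[0], key[1], consequence[key], evidence[key], des)
            )
        except ValueError as exc:
            raise RowError(f"{path}: {exc}") from exc
    return records


def write_variant_annotations(records: Iterable[VariantRecord], path) -> None:
    """Write records one row per (rsid, gene, drug); drug-less records get one row."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_VARIANT_COLUMNS)
        for rec in records:
            base = [rec.rsid, rec.gene, rec.consequence, str(rec.evidence_category)]
            if rec.drug_effects:
                for de in rec.drug_effects:
                    writer.writerow(base + [de.drug, _EFFECT_SEP.join(sorted(de.effect_types))])
            else:
                writer.writerow(base + ["", ""])


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------


def read_score_table(path, tools: list[str] | None = None,
                     columns: Mapping[str, str] | None = None) -> ToolScoreTable:
    """Read a dbNSFP-style per-tool score TSV.

    Empty cells and the literal token ``NA`` are missing values.  Any other
    non-numeric cell raises :class:`RowError` with row/column coordinates.
    """
    tools = list(tools if tools is not None else DEFAULT_TOOLS)
    rows = _open_table(path, tuple(["rsid", "group", *tools]), columns)
    rsids, groups, data = [], [], []
    for lineno, row in rows:
        rsids.append(row["rsid"])
        groups.append(row["group"])
        vals = []
        for tool in tools:
            cell = row[tool]
            if cell in _MISSING_TOKENS:
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise RowError(
                        f"line {lineno}, column {tool!r}: non-numeric score {cell!r}"
                    ) from None
        data.append(vals)
    scores = pd.DataFrame(data, index=pd.Index(rsids, name="rsid"), columns=tools, dtype=float)
    group_s = pd.Series(groups, index=scores.index, name="group", dtype=object)
    return ToolScoreTable(tools, scores, group_s)


def write_score_table(table: ToolScoreTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rsid", "group", *table.tools])
        for rsid in table.scores.index:
            row = [rsid, table.groups.loc[rsid]]
            for tool in table.tools:
                v = table.scores.at[rsid, tool]
                row.append("NA" if pd.isna(v) else np.format_float_positional(v, trim="-"))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# gene annotations, ClinVar presence, truth labels
# ---------------------------------------------------------------------------


def read_gene_annotations(adme_path, go_path) -> GeneAnnotationMap:
    """Build gene annotations from a PharmaADME-style list and a gene->GO-term TSV.

    Genes present in either file get an entry; all other genes resolve to the
    default annotation (``is_adme=False``, no GO terms) via
    :meth:`GeneAnnotationMap.get`.
    """
    adme: set[str] = set()
    with open(adme_path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                adme.add(sym.upper())
    go: dict[str, set[str]] = {}
    with open(go_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for raw in reader:
            if not raw or raw[0].lstrip().startswith("#"):
                continue
            if len(raw) < 2:
                raise SchemaError(f"{go_path}: expected (gene, term) rows, got {raw!r}")
            gene, term = raw[0].strip(), raw[1].strip()
            if gene and term:
                go.setdefault(gene.upper(), set()).add(term)
    annotations = [
        GeneAnnotation(sym, sym in adme, frozenset(go.get(sym, set())))
        for sym in sorted(adme | set(go))
    ]
    return GeneAnnotationMap(annotations)


def write_gene_annotations(genes: GeneAnnotationMap, adme_path, go_path) -> None:
    with open(adme_path, "w", encoding="utf-8") as fh:
        for sym in sorted(genes):
            if genes[sym].is_adme:
                fh.write(sym + "\n")
    with open(go_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for sym in sorted(genes):
            for term in sorted(genes[sym].go_terms):
                writer.writerow([sym, term])


def read_clinvar_set(path) -> set[str]:
    """Read a plain-text rsID list (one per line, '#' comments allowed)."""
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            rsid = line.split("#", 1)[0].strip()
            if rsid:
                out.add(rsid)
    return out


def write_clinvar_set(rsids: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rsid in sorted(rsids):
            fh.write(rsid + "\n")


_LABEL_ALIASES = {"typea": "TypeA", "typeb": "TypeB", "type a": "TypeA", "type b": "TypeB"}


def read_truth_set(path, columns: Mapping[str, str] | None = None) -> list[TruthLabel]:
    """Read the manually curated Type A / Type B truth labels, in file order."""
    required = ("rsid", "label")
    rows = _open_table(path, required, columns)
    # rationale column is optional; re-read it if present
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter="\t"))
    has_rationale = "rationale" in header
    if has_rationale:
        rows = _open_table(path, ("rsid", "label", "rationale"), columns)
    labels, seen = [], set()
    for lineno, row in rows:
        token = row["label"].strip().lower()
        if token not in _LABEL_ALIASES:
            raise SchemaError(f"line {lineno}: unknown label token {row['label']!r}")
        if row["rsid"] in seen:
            raise SchemaError(f"duplicate rsid {row['rsid']!r} in truth set")
        seen.add(row["rsid"])
        labels.append(
            TruthLabel(row["rsid"], _LABEL_ALIASES[token], row.get("rationale", ""))
        )
    return labels


def write_truth_set(labels: Iterable[TruthLabel], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rsid", "label", "rationale"])
        for lab in labels:
            writer.writerow([lab.rsid, lab.label, lab.rationale])
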