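"""Gene neighborhoods and the functional-category rule engine.

A neighborhood is a maximal run of annotated genes on one contig in which
consecutive annotated genes are separated by at most ``max_gap`` ordinal
gene indices (default 3) — the connected components of the co-location
graph.  Neighborhood membership, not nucleotide distance, is what the
operon rules quantify: a complete mtrCAB in one neighborhood marks
dissimilatory iron reduction, mtrAB without mtrC only "probable" reduction,
a mam magnetosome operon counts as present when at least half of its ten
marker families are co-located, and so on.

The ruleset ships as a data file (one rule per line) codifying the
published main-text logic; users can override it without code changes.
Complete-operon rules shadow their partial fallbacks declaratively through
each rule's forbidden-family list, so evaluation order never matters.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .annotate import GeneAnnotation
from .config import get_default
from .family_db import CATEGORY_SCHEMA, FamilyDatabase, ManifestError

_EPS = 1e-12


@dataclass(frozen=True)
class Neighborhood:
    contig_id: str
    members: tuple[GeneAnnotation, ...]  # ordered by gene index

    @property
    def families(self) -> frozenset:
        out: set[str] = set()
        for a in self.members:
            out |= a.families
        return frozenset(out)

    @property
    def span(self) -> tuple[int, int]:
        return self.members[0].index, self.members[-1].index

    def genes_with_family(self, family_id: str) -> list[str]:
        return [a.gene_id for a in self.members if family_id in a.families]


@dataclass(frozen=True)
class CategoryCall:
    sample_id: str
    category: str
    rule_id: str
    evidence: tuple[tuple[str, str], ...]  # (family_id, gene_id) pairs
    contig_id: str
    completeness: float | None = None
    flags: frozenset = frozenset()

    @property
    def evidence_families(self) -> frozenset:
        return frozenset(f for f, _ in self.evidence)

    @property
    def evidence_genes(self) -> frozenset:
        return frozenset(g for _, g in self.evidence)


def build_neighborhoods(
    annotations: list[GeneAnnotation], max_gap: int | None = None
) -> list[Neighborhood]:
    """Group annotations into neighborhoods (order-invariant, deterministic)."""
    if max_gap is None:
        max_gap = get_default("neighborhoods", "max_gap")
    if max_gap < 1:
        raise ValueError(f"max_gap must be >= 1, got {max_gap}")
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        by_contig.setdefault(a.contig_id, []).append(a)
    out: list[Neighborhood] = []
    for contig in sorted(by_contig):
        members = sorted(by_contig[contig], key=lambda a: a.index)
        run: list[GeneAnnotation] = []
        for a in members:
            if run and a.index - run[-1].index > max_gap:
                out.append(Neighborhood(contig, tuple(run)))
                run = []
            run.append(a)
        if run:
            out.append(Neighborhood(contig, tuple(run)))
    return out


def operon_completeness(nb: Neighborhood, od) -> float:
    """Fraction of an operon's member families found in the neighborhood."""
    present = nb.families & set(od.member_families)
    return len(present) / len(od.member_families)


# ---------------------------------------------------------------------------
# ruleset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    rule_id: str
    category: str
    required: frozenset
    members: tuple[str, ...]
    min_present: int  # resolved absolute count over `members`
    forbidden: frozenset
    scope: str  # neighborhood | gene


@dataclass
class RuleSet:
    rules: list[Rule] = field(default_factory=list)

    def validate(self, db: FamilyDatabase) -> None:
        for r in self.rules:
            if r.category not in CATEGORY_SCHEMA:
                raise ManifestError(f"rule {r.rule_id}: unknown category {r.category!r}")
            for fam in (*r.required, *r.members, *r.forbidden):
                if fam not in db.records:
                    raise ManifestError(f"rule {r.rule_id}: unknown family {fam!r}")


_RULE_COLUMNS = [
    "rule_id", "category", "required_families", "member_families",
    "min_present", "forbidden_families", "scope",
]


def _split(tok: str) -> list[str]:
    tok = tok.strip()
    if not tok or tok == "-":
        return []
    return [t for t in tok.split(",") if t]


def parse_ruleset(text: str, db: FamilyDatabase) -> RuleSet:
    """Parse the rules TSV.  ``@category:<label>`` in a family list expands
    to every family of that category; ``min_present`` may be an absolute
    count or a fraction (value containing '.' or '/') of the member list."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header != _RULE_COLUMNS:
        raise ManifestError(f"ruleset: expected columns {_RULE_COLUMNS}")
    rules: list[Rule] = []
    for ln in lines[1:]:
        vals = ln.split("\t")
        vals += [""] * (len(header) - len(vals))
        row = dict(zip(header, vals))

        def expand(tokens: list[str]) -> list[str]:
            out: list[str] = []
            for t in tokens:
                if t.startswith("@category:"):
                    label = t.split(":", 1)[1]
                    if label not in CATEGORY_SCHEMA:
                        raise ManifestError(f"rule {row['rule_id']}: unknown category macro {t!r}")
                    out.extend(f.family_id for f in db.families_in_category(label))
                else:
                    out.append(t)
            return out

        required = frozenset(expand(_split(row["required_families"])))
        members = tuple(expand(_split(row["member_families"])))
        tok = row["min_present"].strip()
        if not tok or tok == "-":
            min_present = 0
        elif "." in tok or "/" in tok:
            if "/" in tok:
                num, den = tok.split("/")
                frac = float(num) / float(den)
            else:
                frac = float(tok)
            min_present = max(1, math.ceil(frac * len(members) - _EPS))
        else:
            min_present = int(tok)
        rules.append(
            Rule(
                rule_id=row["rule_id"],
                category=row["category"],
                required=required,
                members=members,
                min_present=min_present,
                forbidden=frozenset(_split(row["forbidden_families"])),
                scope=row["scope"],
            )
        )
    rs = RuleSet(rules)
    rs.validate(db)
    return rs


def default_ruleset(db: FamilyDatabase) -> RuleSet:
    text = resources.files("ferroscan.data").joinpath("rules.tsv").read_text()
    return parse_ruleset(text, db)


# ---------------------------------------------------------------------------
# rule evaluation
# ---------------------------------------------------------------------------

def apply_rules(
    neighborhoods: list[Neighborhood],
    db: FamilyDatabase,
    ruleset: RuleSet | None = None,
    sample_id: str = "sample",
) -> list[CategoryCall]:
    """Evaluate the ruleset over neighborhoods; pure and deterministic.

    Neighborhood-scope rules fire once per neighborhood when all required
    families are present, at least ``min_present`` member families are
    present, and no forbidden family is present.  Gene-scope rules fire
    once per annotated gene matching a listed family.  Siderophore-synthesis
    genes outside any fired synthesis-operon call are reported as gene-level
    calls flagged ``low_confidence``.
    """
    if ruleset is None:
        ruleset = default_ruleset(db)

    calls: list[CategoryCall] = []
    synthesis_covered: set[str] = set()  # gene ids covered by an operon call

    for nb in neighborhoods:
        present = nb.families
        for rule in ruleset.rules:
            if rule.scope != "neighborhood":
                continue
            if not rule.required <= present:
                continue
            member_hits = [m for m in rule.members if m in present]
            if len(member_hits) < rule.min_present:
                continue
            if rule.forbidden & present:
                continue
            ev_families = sorted(rule.required | set(member_hits))
            evidence = tuple(
                (fam, gene) for fam in ev_families for gene in nb.genes_with_family(fam)
            )
            universe = rule.required | set(rule.members)
            completeness = None
            if len(universe) > 1:
                completeness = len(universe & present) / len(universe)
            calls.append(
                CategoryCall(
                    sample_id=sample_id,
                    category=rule.category,
                    rule_id=rule.rule_id,
                    evidence=evidence,
                    contig_id=nb.contig_id,
                    completeness=completeness,
                )
            )
            if rule.category == "siderophore_synthesis":
                synthesis_covered.update(g for _, g in evidence)

    # gene-scope rules
    gene_rules = [r for r in ruleset.rules if r.scope == "gene"]
    for nb in neighborhoods:
        for a in nb.members:
            for rule in gene_rules:
                fams = rule.required | set(rule.members)
                matched = sorted(a.families & fams)
                if not matched:
                    continue
                calls.append(
                    CategoryCall(
                        sample_id=sample_id,
                        category=rule.category,
                        rule_id=rule.rule_id,
                        evidence=tuple((f, a.gene_id) for f in matched),
                        contig_id=nb.contig_id,
                    )
                )

    # siderophore-synthesis singletons -> low-confidence gene calls
    for nb in neighborhoods:
        for a in nb.members:
            if a.category != "siderophore_synthesis" or a.gene_id in synthesis_covered:
                continue
            calls.append(
                CategoryCall(
                    sample_id=sample_id,
                    category="siderophore_synthesis",
                    rule_id="sid_singleton",
                    evidence=((a.family_id, a.gene_id),),
                    contig_id=nb.contig_id,
                    flags=frozenset({"low_confidence"}),
                )
            )
    calls.sort(key=lambda c: (c.contig_id, c.category, c.rule_id, c.evidence))
    return calls


def write_calls_csv(calls: list[CategoryCall], path: str | Path, append: bool = False) -> None:
    mode = "a" if append else "w"
    write_header = not (append and Path(path).exists() and Path(path).stat().st_size > 0)
    with open(path, mode, newline="") as fh:
        writer = csv.writer(fh)
        if write_header:
            writer.writerow(["sample", "contig", "category", "rule_id", "completeness", "flags", "evidence"])
        for c in calls:
            writer.writerow([
                c.sample_id, c.contig_id, c.category, c.rule_id,
                "" if c.completeness is None else f"{c.completeness:.6g}",
                ";".join(sorted(c.flags)),
                ";".join(f"{f}:{g}" for f, g in c.evidence),
            ])
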