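"""The family manifest: detection models, categories, cutoffs, operons.

The manifest is a TSV binding each protein family to its functional
category, detection method (profile HMM or homology fallback), acceptance
cutoff and optional special filters (minimum length, minimum heme-motif
count) plus operon membership.  The shipped default manifest is a faithful
skeleton of the published family table — family ids, the 12-category
schema, operon groups and the special Cyc2 filter — backed by *toy* models:
profile HMMs and homology reference sequences generated deterministically
from each family id.  The real curated model library is mounted by pointing
:func:`load_manifest` at a user manifest + model directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .profile_hmm import ProfileHMM, parse_hmmer3
from .synthetic_fixtures import (
    AMINO_ALPHABET,
    HEME_MOTIF_CORE,
    make_toy_hmm,
    stable_seed,
)

#: the fixed, ordered 12-category schema
CATEGORY_SCHEMA: tuple[str, ...] = (
    "iron_transport",
    "heme_oxygenase",
    "heme_transport",
    "siderophore_synthesis",
    "siderophore_transport",
    "iron_gene_regulation",
    "iron_oxidation",
    "possible_iron_oxidation_and_possible_iron_reduction",
    "iron_reduction",
    "probable_iron_reduction",
    "iron_storage",
    "magnetosome_formation",
)


class ManifestError(ValueError):
    """Raised when a manifest or ruleset fails validation."""


@dataclass(frozen=True)
class FamilyRecord:
    family_id: str
    category: str
    method: str  # {"hmm", "homology"}
    model_ref: str
    bit_cutoff: float | None = None
    evalue_cutoff: float | None = None
    min_length: int | None = None
    min_heme_motifs: int | None = None
    operon_group: str | None = None
    source: str = "custom"
    tags: frozenset = frozenset()

    def __post_init__(self):
        if self.category not in CATEGORY_SCHEMA:
            raise ManifestError(
                f"family {self.family_id}: unknown category {self.category!r}; "
                f"allowed: {', '.join(CATEGORY_SCHEMA)}"
            )
        if self.method not in {"hmm", "homology"}:
            raise ManifestError(f"family {self.family_id}: unknown method {self.method!r}")
        if self.method == "hmm" and (self.bit_cutoff is None or self.evalue_cutoff is not None):
            raise ManifestError(f"family {self.family_id}: hmm method requires a bit cutoff only")
        if self.method == "homology" and (self.evalue_cutoff is None or self.bit_cutoff is not None):
            raise ManifestError(f"family {self.family_id}: homology method requires an e-value cutoff only")


@dataclass(frozen=True)
class OperonDef:
    operon_id: str
    member_families: tuple[str, ...]
    min_fraction: float = 1.0
    anchors: frozenset = frozenset()
    partial_subsets: tuple[frozenset, ...] = ()
    category_on_success: str = ""
    category_on_partial: str | None = None

    def __post_init__(self):
        if len(self.member_families) < 2:
            raise ManifestError(f"operon {self.operon_id}: needs at least 2 member families")
        if not 0 < self.min_fraction <= 1:
            raise ManifestError(f"operon {self.operon_id}: min_fraction outside (0, 1]")

    def partial_trigger(self, present: set[str]) -> bool:
        """Whether a below-threshold member set still triggers the partial fallback."""
        return any(frozenset(present) == sub for sub in self.partial_subsets)


class FamilyDatabase:
    """Validated set of family records, operon definitions and their models."""

    def __init__(
        self,
        records: dict[str, FamilyRecord],
        operons: dict[str, OperonDef],
        hmms: dict[str, ProfileHMM],
        references: dict[str, dict[str, str]],
    ):
        self.records = records
        self.operons = operons
        self._hmms = hmms
        self._references = references
        self.validate()

    @property
    def categories(self) -> tuple[str, ...]:
        """The fixed 12-label category schema."""
        return CATEGORY_SCHEMA

    def validate(self) -> None:
        for fam in self.records.values():
            if fam.method == "hmm":
                if fam.model_ref not in self._hmms:
                    raise ManifestError(f"family {fam.family_id}: missing HMM {fam.model_ref!r}")
            else:
                refs = self._references.get(fam.family_id)
                if not refs:
                    raise ManifestError(f"family {fam.family_id}: missing reference sequences")
        for od in self.operons.values():
            for m in od.member_families:
                if m not in self.records:
                    raise ManifestError(f"operon {od.operon_id}: unknown member family {m!r}")
            if od.category_on_success not in CATEGORY_SCHEMA:
                raise ManifestError(f"operon {od.operon_id}: unknown category {od.category_on_success!r}")
            if od.category_on_partial and od.category_on_partial not in CATEGORY_SCHEMA:
                raise ManifestError(f"operon {od.operon_id}: unknown partial category")

    # -- lookups ---------------------------------------------------------
    def operon(self, operon_id: str) -> OperonDef:
        try:
            return self.operons[operon_id]
        except KeyError:
            raise KeyError(f"unknown operon {operon_id!r}") from None

    def families_in_category(self, label: str) -> list[FamilyRecord]:
        if label not in CATEGORY_SCHEMA:
            raise KeyError(f"unknown category {label!r}; allowed: {', '.join(CATEGORY_SCHEMA)}")
        return sorted(
            (f for f in self.records.values() if f.category == label),
            key=lambda f: f.family_id,
        )

    def hmm_families(self) -> list[FamilyRecord]:
        return sorted((f for f in self.records.values() if f.method == "hmm"), key=lambda f: f.family_id)

    def homology_families(self) -> list[FamilyRecord]:
        return sorted((f for f in self.records.values() if f.method == "homology"), key=lambda f: f.family_id)

    def hmm_for(self, family_id: str) -> ProfileHMM:
        fam = self.records[family_id]
        hmm = self._hmms[fam.model_ref]
        hmm.bit_cutoff = fam.bit_cutoff
        return hmm

    def references_for(self, family_id: str) -> dict[str, str]:
        return self._references[family_id]

    def consensus_for(self, family_id: str) -> str:
        """Consensus (modal) sequence of a family's profile HMM."""
        hmm = self.hmm_for(family_id)
        return "".join(AMINO_ALPHABET[i] for i in np.argmax(hmm.match_emit, axis=1))


# ---------------------------------------------------------------------------
# manifest / operon parsing
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "family_id", "category", "method", "model_ref", "cutoff",
    "min_length", "min_heme_motifs", "operon_group", "source", "tags",
]


def _parse_fraction(tok: str) -> float:
    if "/" in tok:
        num, den = tok.split("/")
        return float(num) / float(den)
    return float(tok)


def _read_tsv(text: str, required_cols: list[str], what: str) -> list[dict]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ManifestError(f"{what}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in required_cols if c not in header]
    if missing:
        raise ManifestError(f"{what}: missing column(s) {missing}")
    rows = []
    for ln in lines[1:]:
        vals = ln.rstrip("\n").split("\t")
        vals += [""] * (len(header) - len(vals))
        rows.append(dict(zip(header, vals)))
    return rows


def parse_manifest_rows(text: str) -> list[FamilyRecord]:
    rows = _read_tsv(text, _MANIFEST_COLUMNS, "manifest")
    records: list[FamilyRecord] = []
    seen: set[str] = set()
    for row in rows:
        fid = row["family_id"]
        if fid in seen:
            raise ManifestError(f"duplicate family_id {fid!r}")
        seen.add(fid)
        method = row["method"]
        cutoff = float(row["cutoff"])
        records.append(
            FamilyRecord(
                family_id=fid,
                category=row["category"],
                method=method,
                model_ref=row["model_ref"],
                bit_cutoff=cutoff if method == "hmm" else None,
                evalue_cutoff=cutoff if method == "homology" else None,
                min_length=int(row["min_length"]) if row["min_length"] else None,
                min_heme_motifs=int(row["min_heme_motifs"]) if row["min_heme_motifs"] else None,
                operon_group=row["operon_group"] or None,
                source=row["source"] or "custom",
                tags=frozenset(t for t in row["tags"].split(",") if t),
            )
        )
    return records


_OPERON_COLUMNS = [
    "operon_id", "members", "min_fraction", "anchors", "partial_members",
    "category_on_success", "category_on_partial",
]


def parse_operon_rows(text: str) -> dict[str, OperonDef]:
    rows = _read_tsv(text, _OPERON_COLUMNS, "operon table")
    operons: dict[str, OperonDef] = {}
    for row in rows:
        oid = row["operon_id"]
        if oid in operons:
            raise ManifestError(f"duplicate operon_id {oid!r}")
        partial = tuple(
            frozenset(chunk.split("+")) for chunk in row["partial_members"].split("|") if chunk
        )
        operons[oid] = OperonDef(
            operon_id=oid,
            member_families=tuple(row["members"].split(",")),
            min_fraction=_parse_fraction(row["min_fraction"]) if row["min_fraction"] else 1.0,
            anchors=frozenset(a for a in row["anchors"].split(",") if a),
            partial_subsets=partial,
            category_on_success=row["category_on_success"],
            category_on_partial=row["category_on_partial"] or None,
        )
    return operons


def load_manifest(
    manifest_path: str | Path,
    model_dir: str | Path,
    operon_path: str | Path | None = None,
) -> FamilyDatabase:
    """Load a manifest + model directory into a validated database.

    HMM-method families resolve to ``<model_ref>.hmm`` (HMMER3 ASCII) and
    homology families to ``<model_ref>.faa`` (protein FASTA) inside
    ``model_dir``.
    """
    manifest_path, model_dir = Path(manifest_path), Path(model_dir)
    records = {r.family_id: r for r in parse_manifest_rows(manifest_path.read_text())}
    operons: dict[str, OperonDef] = {}
    if operon_path is not None:
        operons = parse_operon_rows(Path(operon_path).read_text())
    hmms: dict[str, ProfileHMM] = {}
    references: dict[str, dict[str, str]] = {}
    for fam in records.values():
        if fam.method == "hmm":
            if fam.model_ref in hmms:
                continue
            path = model_dir / f"{fam.model_ref}.hmm"
            if not path.exists():
                raise ManifestError(f"family {fam.family_id}: model file {path} not found")
            models = parse_hmmer3(path.read_text())
            for m in models:
                hmms[m.name] = m
            if fam.model_ref not in hmms:
                raise ManifestError(f"{path}: does not contain a model named {fam.model_ref!r}")
        else:
            path = model_dir / f"{fam.model_ref}.faa"
            if not path.exists():
                raise ManifestError(f"family {fam.family_id}: reference file {path} not found")
            from Bio import SeqIO

            references[fam.family_id] = {
                rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
            }
    return FamilyDatabase(records, operons, hmms, references)


# ---------------------------------------------------------------------------
# shipped default (toy-model skeleton)
# ---------------------------------------------------------------------------

_TOY_CONSENSUS_LEN = 18


def toy_consensus(family_id: str, needs_heme_motif: bool = False) -> str:
    """Deterministic toy consensus for a family (pure function of the id)."""
    rng = np.random.default_rng(stable_seed("consensus", family_id))
    if needs_heme_motif:
        # no other cysteines, so the consensus carries exactly one CxxCH
        alphabet = [a for a in AMINO_ALPHABET if a != "C"]
        body = rng.choice(alphabet, size=_TOY_CONSENSUS_LEN)
        mid = _TOY_CONSENSUS_LEN // 2
        return "".join(body[:mid]) + HEME_MOTIF_CORE + "".join(body[mid:])
    return "".join(rng.choice(list(AMINO_ALPHABET), size=_TOY_CONSENSUS_LEN))


def toy_model_for(family: FamilyRecord) -> ProfileHMM:
    cons = toy_consensus(family.family_id, needs_heme_motif=bool(family.min_heme_motifs))
    hmm = make_toy_hmm(cons, match_prob=0.95)
    hmm.name = family.model_ref
    hmm.bit_cutoff = family.bit_cutoff
    return hmm


_REFERENCE_LEN = 250


def toy_references_for(family_id: str, n: int = 2) -> dict[str, str]:
    """Deterministic synthetic reference proteins for a homology family."""
    rng = np.random.default_rng(stable_seed("reference", family_id))
    refs = {}
    core = "".join(rng.choice(list(AMINO_ALPHABET), size=_REFERENCE_LEN))
    refs[f"{family_id}_ref1"] = core
    for k in range(2, n + 1):
        seq = list(core)
        for pos in rng.choice(len(seq), size=len(seq) // 10, replace=False):
            seq[pos] = rng.choice(list(AMINO_ALPHABET))
        refs[f"{family_id}_ref{k}"] = "".join(seq)
    return refs


_default_db: FamilyDatabase | None = None


def default_database() -> FamilyDatabase:
    """The shipped default database: Table-skeleton manifest + toy models."""
    global _default_db
    if _default_db is None:
        data = resources.files("ferroscan.data")
        records = {r.family_id: r for r in parse_manifest_rows(data.joinpath("manifest.tsv").read_text())}
        operons = parse_operon_rows(data.joinpath("operons.tsv").read_text())
        hmms = {}
        references = {}
        for fam in records.values():
            if fam.method == "hmm":
                hmms[fam.model_ref] = toy_model_for(fam)
            else:
                references[fam.family_id] = toy_references_for(fam.family_id)
        _default_db = FamilyDatabase(records, operons, hmms, references)
    return _default_db


def write_model_library(db: FamilyDatabase, model_dir: str | Path) -> None:
    """Materialise a database's models as files consumable by load_manifest."""
    from .profile_hmm import write_hmmer3

    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    for fam in db.records.values():
        if fam.method == "hmm":
            (model_dir / f"{fam.model_ref}.hmm").write_text(write_hmmer3(db.hmm_for(fam.family_id)))
        else:
            with open(model_dir / f"{fam.model_ref}.faa", "w") as fh:
                for rid, seq in db.references_for(fam.family_id).items():
                    fh.write(f">{rid}\n{seq}\n")
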