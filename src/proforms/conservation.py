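"""Cross-species transfer of modification-site evidence through an MSA.

A modified-form hypothesis (e.g. a multiply phosphorylated kinase form
characterized in human) is tested in another species by mapping each of
its sites through a multiple sequence alignment and applying evidence
rules:

* **curated** — an organism-specific term for the form already exists in
  the target species (it is in the curated registry);
* **absent** — at least one *required* site (confirmed in vivo in the
  reference species) is not conserved in the target;
* **predicted** — every required site is conserved *and* at least one
  piece of corroborating evidence exists: an in vivo or high-throughput
  phosphosite reported in the target at one of the mapped positions, or
  a demonstrated analogous kinase event supplied as an evidence tag;
* **insufficient_evidence** — the sites are conserved but nothing
  corroborates the form in the target.

Coordinates are 1-based throughout: residue positions on the ungapped
sequences and alignment columns alike.  The gap character is ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO

__all__ = [
    "Alignment",
    "ModSite",
    "FormSite",
    "ModForm",
    "SiteVerdict",
    "ConservationCall",
    "AlignmentError",
    "read_alignment",
    "infer_form",
    "annotate_alignment",
    "EVIDENCE_TIERS",
    "CORROBORATION_TAGS",
    "STATUSES",
]

GAP = "-"
EVIDENCE_TIERS = ("in_vivo", "in_vitro", "high_throughput", "predicted")
CORROBORATION_TAGS = (
    "target_htp_site",
    "target_in_vivo_site",
    "analogous_kinase_demonstrated",
)
STATUSES = ("curated", "predicted", "insufficient_evidence", "absent")

#: corroborating tiers for a site observed in the target species
_CORROBORATING_TIERS = {"in_vivo": "target_in_vivo_site", "high_throughput": "target_htp_site"}


class AlignmentError(ValueError):
    pass


class Alignment:
    """Equal-length gapped rows over the amino-acid alphabet plus ``-``."""

    def __init__(self, rows: Mapping[str, str] | Sequence[tuple[str, str]]):
        items = list(rows.items()) if isinstance(rows, Mapping) else list(rows)
        if not items:
            raise AlignmentError("empty alignment")
        self.ids = [sid for sid, _ in items]
        self.rows = {sid: seq.upper() for sid, seq in items}
        if len(self.ids) != len(set(self.ids)):
            raise AlignmentError("duplicate sequence ids")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal row lengths: {sorted(lengths)}")
        (self.n_columns,) = lengths
        # per sequence: ungapped position (1-based) -> column (1-based)
        self._col_of: dict[str, list[int]] = {}
        # per sequence: column (1-based) -> ungapped position or 0 at gaps
        self._pos_at: dict[str, list[int]] = {}
        for sid, seq in self.rows.items():
            cols: list[int] = []
            pos_at = [0] * (self.n_columns + 1)
            p = 0
            for c, ch in enumerate(seq, start=1):
                if ch != GAP:
                    p += 1
                    cols.append(c)
                    pos_at[c] = p
            self._col_of[sid] = cols
            self._pos_at[sid] = pos_at

    # -- accessors ---------------------------------------------------------
    def ungapped(self, seq_id: str) -> str:
        return self.rows[self._check_id(seq_id)].replace(GAP, "")

    def ungapped_length(self, seq_id: str) -> int:
        return len(self._col_of[self._check_id(seq_id)])

    def residue(self, seq_id: str, position: int) -> str:
        """Residue at a 1-based ungapped position."""
        return self.rows[seq_id][self.column_of(seq_id, position) - 1]

    def column_of(self, seq_id: str, position: int) -> int:
        """Alignment column (1-based) of an ungapped residue position."""
        cols = self._col_of[self._check_id(seq_id)]
        if not 1 <= position <= len(cols):
            raise AlignmentError(
                f"position {position} out of range 1..{len(cols)} for {seq_id}"
            )
        return cols[position - 1]

    def position_at(self, seq_id: str, column: int) -> int | None:
        """Ungapped position at a column, or None when the column is a gap."""
        self._check_id(seq_id)
        if not 1 <= column <= self.n_columns:
            raise AlignmentError(f"column {column} out of range 1..{self.n_columns}")
        p = self._pos_at[seq_id][column]
        return p or None

    def _check_id(self, seq_id: str) -> str:
        if seq_id not in self.rows:
            raise AlignmentError(f"unknown sequence id {seq_id!r}")
        return seq_id

    # -- coordinate mapping --------------------------------------------------
    def map_position(self, from_id: str, position: int, to_id: str) -> int | None:
        """Map a residue position between rows via its alignment column.

        Returns the 1-based position in ``to_id`` or None when the
        column is a gap there.  Mapping is monotone and self-inverse on
        non-gap columns.
        """
        return self.position_at(to_id, self.column_of(from_id, position))


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Load an aligned FASTA or ClustalW ``.aln`` file."""
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in (".aln", ".clustal") else "fasta"
    msa = AlignIO.read(str(path), fmt)
    return Alignment([(rec.id, str(rec.seq)) for rec in msa])


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in aln.ids:
            fh.write(f">{sid}\n")
            seq = aln.rows[sid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# sites and forms


@dataclass(frozen=True, order=True)
class ModSite:
    """A modification site on an ungapped sequence."""

    seq_id: str
    position: int
    residue: str
    modification: str = "phosphorylation"
    evidence_tier: str = "in_vivo"

    def validate(self, aln: Alignment) -> None:
        if self.position < 1:
            raise AlignmentError(f"{self}: position must be >= 1")
        if self.evidence_tier not in EVIDENCE_TIERS:
            raise AlignmentError(f"{self}: unknown evidence tier")
        actual = aln.residue(self.seq_id, self.position)
        if actual != self.residue.upper():
            raise AlignmentError(
                f"{self.seq_id} position {self.position}: sequence has "
                f"{actual}, site says {self.residue}"
            )


@dataclass(frozen=True)
class FormSite:
    site: ModSite
    required: bool = True


@dataclass(frozen=True)
class ModForm:
    """A modified-form hypothesis anchored on a reference sequence."""

    form_id: str
    gene: str
    reference_species: str  # sequence id of the reference row
    sites: tuple[FormSite, ...]
    kinase: str | None = None

    def __post_init__(self):
        if not any(fs.required for fs in self.sites):
            raise AlignmentError(f"{self.form_id}: needs at least one required site")
        for fs in self.sites:
            if fs.site.seq_id != self.reference_species:
                raise AlignmentError(
                    f"{self.form_id}: site {fs.site} not on reference sequence"
                )


@dataclass(frozen=True)
class SiteVerdict:
    site: ModSite
    required: bool
    mapped_position: int | None  # None: gap in the target row
    mapped_residue: str | None
    conserved: bool


@dataclass(frozen=True)
class ConservationCall:
    form_id: str
    target_species: str
    status: str
    site_verdicts: tuple[SiteVerdict, ...]
    evidence: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# conservation rules


def _equivalent(a: str, b: str, rule: str) -> bool:
    if rule == "identical":
        return a == b
    if rule == "st_equivalent":
        return a == b or {a, b} <= {"S", "T"}
    raise AlignmentError(f"unknown equivalence rule {rule!r}")


def site_conserved(
    aln: Alignment,
    site: ModSite,
    to_id: str,
    equivalence: str = "identical",
) -> SiteVerdict:
    """Map one site into a target row and judge conservation.

    Conserved iff the column is not a gap in the target and the target
    residue satisfies the equivalence rule (identical by default;
    ``st_equivalent`` treats Ser and Thr as interchangeable phospho-
    acceptors).
    """
    site.validate(aln)
    pos = aln.map_position(site.seq_id, site.position, to_id)
    if pos is None:
        return SiteVerdict(site, True, None, None, False)
    res = aln.residue(to_id, pos)
    ok = _equivalent(site.residue.upper(), res, equivalence)
    return SiteVerdict(site, True, pos, res, ok)


def infer_form(
    aln: Alignment,
    form: ModForm,
    target_species: str,
    corroborating: Iterable[ModSite] = (),
    curated_registry: Iterable[tuple[str, str]] = (),
    evidence_tags: Iterable[str] = (),
    equivalence: str = "identical",
) -> ConservationCall:
    """Classify a form in a target species (see module docstring).

    ``curated_registry`` holds ``(form_id, species)`` pairs for forms
    already curated; ``corroborating`` lists sites observed in other
    species with their evidence tiers; ``evidence_tags`` passes
    non-site evidence such as ``analogous_kinase_demonstrated``.
    """
    if form.reference_species not in aln.rows:
        raise AlignmentError(
            f"reference sequence {form.reference_species!r} missing from alignment"
        )
    aln._check_id(target_species)

    verdicts = tuple(
        replace(
            site_conserved(aln, fs.site, target_species, equivalence),
            required=fs.required,
        )
        for fs in form.sites
    )

    evidence: list[str] = []
    for tag in evidence_tags:
        if tag not in CORROBORATION_TAGS:
            raise AlignmentError(f"unknown evidence tag {tag!r}")
        evidence.append(tag)
    mapped = {v.mapped_position for v in verdicts if v.mapped_position is not None}
    for s in sorted(corroborating):
        tag = _CORROBORATING_TIERS.get(s.evidence_tier)
        if tag and s.seq_id == target_species and s.position in mapped:
            evidence.append(tag)
    evidence_t = tuple(dict.fromkeys(evidence))  # dedup, stable order

    if (form.form_id, target_species) in set(curated_registry):
        status = "curated"
    elif not all(v.conserved for v in verdicts if v.required):
        status = "absent"
    elif evidence_t:
        status = "predicted"
    else:
        status = "insufficient_evidence"
    return ConservationCall(form.form_id, target_species, status, verdicts, evidence_t)


# ---------------------------------------------------------------------------
# Jalview sequence-features output

_FEATURE_COLOURS = {
    "experimental_phosphosite": "0000ff",
    "predicted_phosphosite": "ff0000",
}


def annotate_alignment(
    aln: Alignment,
    calls: Iterable[ConservationCall] = (),
    sites: Iterable[ModSite] = (),
) -> str:
    """Jalview sequence-features text marking experimental and predicted
    sites.

    Experimental features come from ``sites`` (any non-``predicted``
    tier); predicted features are the mapped positions of conserved
    required sites in calls with status ``predicted``.  Every emitted
    position is validated against the ungapped target sequence.
    """
    lines = [f"{name}\t{colour}" for name, colour in _FEATURE_COLOURS.items()]
    rows: list[tuple[str, str, int, str]] = []
    for s in sorted(set(sites)):
        if s.evidence_tier == "predicted":
            continue
        s.validate(aln)
        rows.append((s.seq_id, f"{s.modification} ({s.evidence_tier})",
                     s.position, "experimental_phosphosite"))
    for call in calls:
        if call.status != "predicted":
            continue
        for v in call.site_verdicts:
            if v.required and v.conserved and v.mapped_position is not None:
                if not 1 <= v.mapped_position <= aln.ungapped_length(call.target_species):
                    raise AlignmentError(
                        f"{call.form_id}: mapped position {v.mapped_position} "
                        f"outside {call.target_species}"
                    )
                rows.append(
                    (call.target_species, f"predicted for {call.form_id}",
                     v.mapped_position, "predicted_phosphosite")
                )
    for seq_id, desc, pos, ftype in sorted(set(rows)):
        lines.append(f"{desc}\t{seq_id}\t-1\t{pos}\t{pos}\t{ftype}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# plain-text table IO (sites, forms, registry)


def write_sites_tsv(sites: Iterable[ModSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tposition\tresidue\tmodification\tevidence_tier\n")
        for s in sorted(set(sites)):
            fh.write(
                f"{s.seq_id}\t{s.position}\t{s.residue}\t{s.modification}\t{s.evidence_tier}\n"
            )


def read_sites_tsv(path: str | Path) -> list[ModSite]:
    out = []
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        sid, pos, res, mod, tier = line.split("\t")
        out.append(ModSite(sid, int(pos), res, mod, tier))
    return out


def write_forms_tsv(forms: Iterable[ModForm], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "form_id\tgene\treference_species\tposition\tresidue\t"
            "evidence_tier\trequired\tkinase\n"
        )
        for f in forms:
            for fs in f.sites:
                fh.write(
                    f"{f.form_id}\t{f.gene}\t{f.reference_species}\t"
                    f"{fs.site.position}\t{fs.site.residue}\t"
                    f"{fs.site.evidence_tier}\t{int(fs.required)}\t{f.kinase or ''}\n"
                )


def read_forms_tsv(path: str | Path) -> list[ModForm]:
    grouped: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        fid, gene, ref, pos, res, tier, req, kinase = line.split("\t")
        g = grouped.setdefault(
            fid, {"gene": gene, "ref": ref, "kinase": kinase or None, "sites": []}
        )
        g["sites"].append(
            FormSite(ModSite(ref, int(pos), res, "phosphorylation", tier), bool(int(req)))
        )
    return [
        ModForm(fid, g["gene"], g["ref"], tuple(g["sites"]), g["kinase"])
        for fid, g in grouped.items()
    ]


def write_registry_tsv(registry: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Rows of (form_id, species_seq_id, curated_term_id)."""
    with open(path, "w") as fh:
        fh.write("form_id\tspecies\tcurated_term_id\n")
        for fid, sp, tid in sorted(set(registry)):
            fh.write(f"{fid}\t{sp}\t{tid}\n")


def read_registry_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        fid, sp, tid = line.split("\t")
        out.append((fid, sp, tid))
    return out
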