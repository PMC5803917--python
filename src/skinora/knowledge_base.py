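"""Pathway knowledge bases: named gene sets plus signed interaction edges.

A knowledge base (KB) plays two roles in the pipeline.  First, the union of
its pathway gene sets is the *universe* against which over-representation
is tested: every contingency-table count refers to genes of this universe,
not to the measured platform.  Second, its signed directed edges
(activation / inhibition / unspecified) are the scaffolding onto which
fold-change states are overlaid for mechanistic reading.

Gene sets are read from GMT files (tab-separated: name, category,
genes...).  Edges are read from a four-column SIF-like file
(source, relation, target, pathway) where the relation vocabulary is
``activates``, ``inhibits`` or ``interacts``.  Gene symbols are upper-cased
at load time; no alias resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .errors import ParseError, ValidationError

SIGN_ACTIVATION = "activation"
SIGN_INHIBITION = "inhibition"
SIGN_UNSPECIFIED = "unspecified"

#: mapping from edge-file relation strings to edge signs
RELATION_TO_SIGN = {
    "activates": SIGN_ACTIVATION,
    "inhibits": SIGN_INHIBITION,
    "interacts": SIGN_UNSPECIFIED,
}


@dataclass(frozen=True)
class Pathway:
    """A named, non-empty gene set with a free-form functional category."""

    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"pathway {self.name!r} has an empty gene set")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class InteractionEdge:
    """A signed directed molecular interaction within one pathway."""

    source: str
    target: str
    sign: str
    pathway: str


@dataclass
class KnowledgeBase:
    """Collection of pathways and interaction edges.

    The enrichment universe is derived, never stored: it is recomputed from
    the pathway gene sets so it can never drift out of sync.
    """

    pathways: dict[str, Pathway] = field(default_factory=dict)
    edges: list[InteractionEdge] = field(default_factory=list)

    @property
    def universe(self) -> frozenset[str]:
        """Union of all pathway gene sets (each gene counted once)."""
        out: set[str] = set()
        for pw in self.pathways.values():
            out |= pw.genes
        return frozenset(out)

    @property
    def pathway_names(self) -> list[str]:
        return sorted(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __contains__(self, name: str) -> bool:
        return name in self.pathways

    def __getitem__(self, name: str) -> Pathway:
        return self.pathways[name]

    def edges_of(self, pathway: str) -> list[InteractionEdge]:
        return [e for e in self.edges if e.pathway == pathway]

    def add_pathway(self, pathway: Pathway) -> None:
        if pathway.name in self.pathways:
            raise ValidationError(f"duplicate pathway name {pathway.name!r}")
        self.pathways[pathway.name] = pathway


def load_gene_sets(path) -> KnowledgeBase:
    """Read a GMT file (name, category, genes...) into a :class:`KnowledgeBase`.

    Gene symbols are upper-cased and de-duplicated within each line.  Blank
    lines are skipped.  An empty file yields an empty KB; the enrichment
    layer refuses an empty universe.
    """
    kb = KnowledgeBase()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, category, genes...), got {len(fields)}"
                )
            name, category = fields[0], fields[1]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ParseError(f"{path}: line {lineno}: pathway {name!r} lists no genes")
            if name in kb.pathways:
                raise ValidationError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            kb.pathways[name] = Pathway(name=name, category=category, genes=genes)
    return kb


def write_gene_sets(kb: KnowledgeBase, path) -> None:
    """Write pathways to GMT; round-trips the pathway → gene-set mapping."""
    with open(path, "wt", encoding="utf-8") as fh:
        for name in kb.pathway_names:
            pw = kb.pathways[name]
            fh.write("\t".join([pw.name, pw.category, *sorted(pw.genes)]) + "\n")


def load_interactions(path, kb: KnowledgeBase) -> KnowledgeBase:
    """Attach edges from a 4-column file (source, relation, target, pathway).

    Unknown relation strings map to ``unspecified`` with a warning.  Every
    edge endpoint must belong to the named pathway's gene set; offending
    lines are collected and reported together.
    """
    edges: list[InteractionEdge] = list(kb.edges)
    seen = set((e.source, e.target, e.sign, e.pathway) for e in edges)
    bad: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields "
                    f"(source, relation, target, pathway), got {len(fields)}"
                )
            source, relation, target, pw_name = (f.strip() for f in fields)
            source, target = source.upper(), target.upper()
            sign = RELATION_TO_SIGN.get(relation)
            if sign is None:
                warnings.warn(
                    f"{path}: line {lineno}: unknown relation {relation!r}; "
                    f"treating as {SIGN_UNSPECIFIED!r}",
                    stacklevel=2,
                )
                sign = SIGN_UNSPECIFIED
            if pw_name not in kb.pathways:
                bad.append(f"line {lineno}: unknown pathway {pw_name!r}")
                continue
            members = kb.pathways[pw_name].genes
            missing = [g for g in (source, target) if g not in members]
            if missing:
                bad.append(
                    f"line {lineno}: {', '.join(missing)} not in pathway {pw_name!r}"
                )
                continue
            key = (source, target, sign, pw_name)
            if key in seen:
                continue
            seen.add(key)
            edges.append(InteractionEdge(source, target, sign, pw_name))
    if bad:
        raise ValidationError(f"{path}: invalid edges:\n  " + "\n  ".join(bad))
    return replace(kb, edges=edges)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: structural violations and size summary."""

    violations: list[tuple[str, str]]
    universe_size: int
    pathway_sizes: dict[str, int]

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("kind\tdetail\n")
            for kind, detail in self.violations:
                fh.write(f"{kind}\t{detail}\n")
            fh.write(f"universe_size\t{self.universe_size}\n")
            for name in sorted(self.pathway_sizes):
                fh.write(f"pathway_size\t{name}={self.pathway_sizes[name]}\n")


def validate(kb: KnowledgeBase) -> ValidationReport:
    """Report (never raise) structural problems in a knowledge base."""
    violations: list[tuple[str, str]] = []
    for name, pw in kb.pathways.items():
        if name != pw.name:
            violations.append(("name_mismatch", f"key {name!r} vs pathway name {pw.name!r}"))
        if not pw.genes:
            violations.append(("empty_pathway", name))
    seen_edges = set()
    for e in kb.edges:
        if e.pathway not in kb.pathways:
            violations.append(("dangling_edge", f"{e.source}->{e.target}: unknown pathway {e.pathway!r}"))
            continue
        members = kb.pathways[e.pathway].genes
        for endpoint in (e.source, e.target):
            if endpoint not in members:
                violations.append(
                    ("dangling_edge", f"{e.source}->{e.target}: {endpoint} not in {e.pathway!r}")
                )
        key = (e.source, e.target, e.sign, e.pathway)
        if key in seen_edges:
            violations.append(("duplicate_edge", f"{e.source}->{e.target} in {e.pathway!r}"))
        seen_edges.add(key)
    return ValidationReport(
        violations=violations,
        universe_size=len(kb.universe),
        pathway_sizes={name: pw.size for name, pw in kb.pathways.items()},
    )


def demo_kb() -> KnowledgeBase:
    """A small skin-biology knowledge base for demonstrations and fixtures.

    Eight pathways assembled from genes with well-described roles in skin
    inflammation, keratinocyte differentiation, barrier formation, wound
    healing, lipid handling and DNA repair, plus a handful of signed edges
    (glucocorticoid-receptor inhibition of TNF, the TNF → TNFRSF1A → TRADD →
    NFKB1 cascade, TLR and CD44/AKT1 routes).  It is a synthetic stand-in
    for a full curated skin knowledge base, sized for fast tests and worked
    examples, not for production analyses.
    """
    sets = {
        "Inflammation": (
            "Basic skin physiology",
            [
                "TNF", "TNFRSF1A", "TRADD", "NFKB1", "NR3C1", "IKBKB",
                "TLR1", "TLR2", "IRAK4", "SMAD4",
                "CXCL1", "CXCL9", "CXCL10", "IL18", "CCL2", "CCL5", "CCL13",
                "CD86", "ICAM1", "VCAM1", "MMP9", "SELE",
                "IL4", "IL4R", "IFNG", "CXCL6", "CXCL16", "CCL8", "CCL24",
                "CCL25", "CCL26",
            ],
        ),
        "Keratinocyte Differentiation": (
            "Epidermal formation",
            [
                "LOR", "FLG", "TGM5", "CDSN", "IVL", "LCE3D", "TGM1", "TGM3",
                "DSG3", "CD44", "AKT1", "PKN2", "PLCG1", "PRKCD", "HRAS",
                "MAP2K3", "JUN", "FOS", "JUND", "FOSL1", "CEBPA", "CEBPB",
                "SP1", "HSPB1", "S100A7", "S100A8", "S100A9", "STAT3", "MYC",
                "MAPK1", "TGFA",
            ],
        ),
        "Wound Healing": (
            "Basic skin physiology",
            ["VEGFA", "PIK3CA", "PLCG1", "MAPK1", "FN1", "EDN1", "PLCB2"],
        ),
        "Barrier Formation": (
            "Epidermal formation",
            ["CTTN", "CDC42", "GRHL3", "AHR", "CLDN1", "TJP1"],
        ),
        "Basal Layer Formation": (
            "Epidermal formation",
            ["LAMA5", "COL4A1", "ITGA6", "ITGB4"],
        ),
        "Lipid Synthesis": (
            "Basic skin physiology",
            [
                "LDLR", "ABCA12", "SPTLC2", "SGMS2", "SMPD2", "NR1H2", "SCD",
                "FASN", "HMGCR", "LPL", "APOC1",
            ],
        ),
        "DNA Damage and Repair": (
            "Stress response",
            [
                "H2AFX", "RAD51", "BRCA2", "MCM3", "DHFR", "HMOX1", "GINS1",
                "PCNA", "CDK1", "CDKN1A", "CCNB1",
            ],
        ),
        "Immune Response": (
            "Basic skin physiology",
            [
                "IL6R", "IL4R", "IL27RA", "IL13RA2", "IL12RB1", "JAK1",
                "STAT3", "STAT6", "SOCS1", "SOCS3", "IL13", "IL6",
            ],
        ),
    }
    kb = KnowledgeBase()
    for name, (category, genes) in sets.items():
        kb.add_pathway(Pathway(name=name, category=category, genes=frozenset(genes)))
    edge_spec = [
        ("NR3C1", SIGN_INHIBITION, "TNF", "Inflammation"),
        ("TNF", SIGN_ACTIVATION, "TNFRSF1A", "Inflammation"),
        ("TNFRSF1A", SIGN_ACTIVATION, "TRADD", "Inflammation"),
        ("TRADD", SIGN_ACTIVATION, "NFKB1", "Inflammation"),
        ("NFKB1", SIGN_ACTIVATION, "CXCL1", "Inflammation"),
        ("NFKB1", SIGN_ACTIVATION, "MMP9", "Inflammation"),
        ("NFKB1", SIGN_ACTIVATION, "SELE", "Inflammation"),
        ("NFKB1", SIGN_ACTIVATION, "ICAM1", "Inflammation"),
        ("TLR2", SIGN_ACTIVATION, "IRAK4", "Inflammation"),
        ("IRAK4", SIGN_ACTIVATION, "NFKB1", "Inflammation"),
        ("NR3C1", SIGN_ACTIVATION, "IKBKB", "Inflammation"),
        ("IKBKB", SIGN_INHIBITION, "NFKB1", "Inflammation"),
        ("CD44", SIGN_ACTIVATION, "AKT1", "Keratinocyte Differentiation"),
        ("AKT1", SIGN_ACTIVATION, "PKN2", "Keratinocyte Differentiation"),
        ("PKN2", SIGN_ACTIVATION, "PLCG1", "Keratinocyte Differentiation"),
        ("PLCG1", SIGN_ACTIVATION, "JUN", "Keratinocyte Differentiation"),
        ("JUN", SIGN_ACTIVATION, "LOR", "Keratinocyte Differentiation"),
        ("JUN", SIGN_ACTIVATION, "S100A7", "Keratinocyte Differentiation"),
        ("CEBPA", SIGN_ACTIVATION, "IVL", "Keratinocyte Differentiation"),
        ("EDN1", SIGN_ACTIVATION, "PLCB2", "Wound Healing"),
        ("SOCS3", SIGN_INHIBITION, "JAK1", "Immune Response"),
    ]
    kb.edges = [
        InteractionEdge(source=s, target=t, sign=sign, pathway=pw)
        for s, sign, t, pw in edge_spec
    ]
    return kb
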