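"""Tunable thresholds of the RGP pipeline.

The defaults encode the published operating point of synteny-break RGP
analysis in enterobacteria: orthologs at >=30% identity over >=80% of the
shorter protein, a 5 kb floor on RGP size, module presence tiers at the
"more than 80% (25%)" rule, and integration hotspots conserved in at least
three genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .errors import ParameterError


@dataclass(frozen=True)
class ParameterSet:
    """Threshold bundle shared by every pipeline stage.

    Attributes
    ----------
    min_identity:
        Minimum percent identity over the aligned region for an ortholog
        pair (default 30).
    min_coverage:
        Minimum aligned fraction of the shorter protein (default 0.8).
    max_gap:
        Maximum number of intervening genes tolerated inside a synteny run,
        on each genome (default 2).
    min_rgp_len:
        Minimum RGP size in bp (default 5000).
    min_missing_run:
        Minimum number of consecutive non-syntenic genes for a missing
        segment; shorter stretches are treated as point noise (default 2).
    presence_hi / presence_lo:
        Module presence tiers: present iff the syntenic-ortholog fraction is
        strictly greater than ``presence_hi``; partial iff strictly greater
        than ``presence_lo`` (defaults 0.8 / 0.25, strict inequalities).
    hotspot_min_genomes:
        Minimum number of genomes with an occupant RGP for a site to count
        as an integration hotspot (default 3).
    trna_flank_window:
        Gene-rank window used for "near a tRNA" adjacency (default 2).
    gc_sd_threshold:
        GC deviation flag threshold in window-SD units (default 2).
    phage_min_genes:
        Minimum count of phage-annotated genes for the prophage heuristic
        (default 5).
    deletion_tolerance_bp:
        Boundary tolerance when matching deletions to modules (default 200).
    atypical_z_threshold:
        z-score above which the compositional score counts as atypical
        (default 3).
    """

    min_identity: float = 30.0
    min_coverage: float = 0.8
    max_gap: int = 2
    min_rgp_len: int = 5000
    min_missing_run: int = 2
    presence_hi: float = 0.8
    presence_lo: float = 0.25
    hotspot_min_genomes: int = 3
    trna_flank_window: int = 2
    gc_sd_threshold: float = 2.0
    phage_min_genes: int = 5
    deletion_tolerance_bp: int = 200
    atypical_z_threshold: float = 3.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "max_gap":  # zero gap tolerance is meaningful
                if v < 0:
                    raise ParameterError(f"max_gap must be >= 0, got {v!r}")
            elif v <= 0:
                raise ParameterError(f"{f.name} must be positive, got {v!r}")
        if not self.presence_lo < self.presence_hi:
            raise ParameterError(
                "presence_lo must be below presence_hi "
                f"({self.presence_lo} >= {self.presence_hi})"
            )
        if not 0 <= self.min_identity <= 100:
            raise ParameterError("min_identity must lie in [0, 100]")
        if not self.min_coverage <= 1:
            raise ParameterError("min_coverage is a fraction in (0, 1]")


# Category tags used by the taxonomic distribution scheme, ordered from the
# narrowest tier outside the strain itself to the widest.
GROUP_CATEGORIES = ("same_genus", "other_genus", "pathogen", "commensal")


@dataclass(frozen=True)
class GroupScheme:
    """Maps genome group categories to distribution-class labels.

    The distribution class of a module is the *widest* tier containing a
    genome (other than the reference itself) where the module is present or
    partially present; a module seen nowhere else is a "strain" module.
    Tier order, narrow to wide: same_genus -> "genus", other_genus ->
    "cross_genus", pathogen -> "pathogens", commensal -> "family".
    """

    strain_label: str = "strain"
    labels: tuple[tuple[str, str], ...] = (
        ("same_genus", "genus"),
        ("other_genus", "cross_genus"),
        ("pathogen", "pathogens"),
        ("commensal", "family"),
    )
    count_partial: bool = True

    def tier(self, category: str) -> int:
        for i, (cat, _) in enumerate(self.labels):
            if cat == category:
                return i
        raise ParameterError(f"unknown group category {category!r}")

    def label_for_tier(self, tier: int) -> str:
        return self.labels[tier][1]

    @property
    def all_labels(self) -> tuple[str, ...]:
        return (self.strain_label,) + tuple(lab for _, lab in self.labels)


DEFAULT_GROUP_SCHEME = GroupScheme()


# ---------------------------------------------------------------------------
# Keyword lexicons (editable config; see classification / modularization).
# Matching is case-insensitive substring search on product strings.
# ---------------------------------------------------------------------------

MOBILITY_LEXICON: dict[str, tuple[str, ...]] = {
    "transposase/IS": ("transposase", "insertion sequence", "is element"),
    "resolvase": ("resolvase",),
    "invertase": ("invertase",),
    "excisionase": ("excisionase",),
    "other recombinase": ("recombinase",),
}

INTEGRASE_KEYWORDS: tuple[str, ...] = ("integrase",)

PHAGE_KEYWORDS: tuple[str, ...] = (
    "phage",
    "capsid",
    "tail",
    "terminase",
    "portal",
    "holin",
    "lysozyme",
    "baseplate",
    "virion",
)

PHAGE_STRUCTURAL_KEYWORDS: tuple[str, ...] = (
    "capsid",
    "tail",
    "terminase",
    "portal",
    "baseplate",
)

# Eight functional classes of modules.  Scan order = tie-break priority.
FUNCTIONAL_CLASSES: tuple[str, ...] = (
    "recombination",
    "phage",
    "antibiotic synthesis",
    "drug resistance",
    "host interaction",
    "environment interaction",
    "metabolism",
    "unknown",
)

FUNCTION_LEXICON: dict[str, tuple[str, ...]] = {
    "recombination": (
        "transposase",
        "integrase",
        "recombinase",
        "resolvase",
        "invertase",
        "excisionase",
    ),
    "phage": PHAGE_KEYWORDS,
    "antibiotic synthesis": (
        "polyketide",
        "peptide synthetase",
        "bacteriocin",
        "antibiotic biosynthesis",
    ),
    "drug resistance": (
        "resistance",
        "efflux",
        "beta-lactamase",
        "multidrug",
    ),
    "host interaction": (
        "virulence",
        "toxin",
        "hemolysin",
        "insecticidal",
        "symbiosis",
    ),
    "environment interaction": (
        "siderophore",
        "iron uptake",
        "adhesin",
        "pilus",
        "fimbrial",
        "secretion system",
        "flagell",
    ),
    "metabolism": (
        "dehydrogenase",
        "synthase",
        "permease",
        "transporter",
        "kinase",
        "reductase",
        "transferase",
        "hydrolase",
        "biosynthesis",
        "metabolism",
    ),
}

RIBOSOMAL_KEYWORDS: tuple[str, ...] = ("ribosomal protein",)
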