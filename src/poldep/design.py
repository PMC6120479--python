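"""Study design and ground-truth effect tables.

A study crosses GFP-tagged polarity *markers* with gene *deletions*. Each
(marker, deletion) combination is imaged as fields of view containing a
mixture of wild-type control cells (carrying a red spindle-pole-body tag)
and deletion cells, so every field is its own internal control.

Ground truth for the synthetic generator is phenomenological: per
combination, positive multipliers on the baseline End1/End2/cytosol
intensities plus an additive shift of the bipolarity parameter. Real
mechanism (motors, microtubules, proteolysis) is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The nine GFP-tagged markers measured in the reference study design.
DEFAULT_MARKERS = (
    "Bud6", "For3", "Mod5", "Myo52", "Tea1", "Tea2", "Tea3", "Tip1", "Tea4",
)

#: The ten deletion genes: the nine marker genes plus mal3.
DEFAULT_DELETIONS = (
    "bud6", "for3", "mod5", "myo52", "tea1", "tea2", "tea3", "tip1", "tea4",
    "mal3",
)


class UnknownEntityError(KeyError):
    """A marker or deletion name outside the study design."""


def marker_gene(marker: str) -> str:
    """Gene symbol (lowercase) encoding a marker protein."""
    return marker.lower()


def deletion_protein(deletion: str) -> str:
    """Protein name (capitalised) encoded by a deleted gene."""
    return deletion.capitalize()


@dataclass(frozen=True)
class StudyDesign:
    """A marker x deletion imaging design.

    ``cells_per_arm`` is the planned number of cells per genotype arm
    (control and deletion separately) for each combination;
    ``fields_per_combination`` how many fields of view carry them.
    Combinations never pair a marker with the deletion of its own gene
    (the tag cannot exist in that strain).
    """

    markers: tuple[str, ...] = DEFAULT_MARKERS
    deletions: tuple[str, ...] = DEFAULT_DELETIONS
    cells_per_arm: int = 100
    fields_per_combination: int = 10

    def __post_init__(self):
        if self.cells_per_arm < 1:
            raise ValueError("cells_per_arm must be >= 1")
        if self.fields_per_combination < 1:
            raise ValueError("fields_per_combination must be >= 1")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker names")
        if len(set(self.deletions)) != len(self.deletions):
            raise ValueError("duplicate deletion names")

    @property
    def combinations(self) -> list[tuple[str, str]]:
        """All valid (marker, deletion) pairs, self-pairs excluded."""
        return [
            (m, d)
            for m in self.markers
            for d in self.deletions
            if d != marker_gene(m)
        ]

    @property
    def planned_cells(self) -> int:
        """Total planned cell count (both arms, all combinations)."""
        return 2 * self.cells_per_arm * len(self.combinations)

    def check_names(self, marker: str, deletion: str) -> None:
        if marker not in self.markers:
            raise UnknownEntityError(f"unknown marker {marker!r}")
        if deletion not in self.deletions:
            raise UnknownEntityError(f"unknown deletion {deletion!r}")


@dataclass(frozen=True)
class GroundTruthEffect:
    """Phenomenological effect of one deletion on one marker.

    Multipliers scale the deletion cells' baseline compartment
    intensities (1.0 = no effect); ``bipolarity_shift`` is added to the
    baseline End2/End1 bipolarity parameter and the result clipped to
    (0, 1).
    """

    marker: str
    deletion: str
    mult_end1: float = 1.0
    mult_end2: float = 1.0
    mult_cyto: float = 1.0
    bipolarity_shift: float = 0.0

    def __post_init__(self):
        for name in ("mult_end1", "mult_end2", "mult_cyto"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not -1.0 <= self.bipolarity_shift <= 1.0:
            raise ValueError("bipolarity_shift must be in [-1, 1]")

    @property
    def is_null(self) -> bool:
        return (
            self.mult_end1 == self.mult_end2 == self.mult_cyto == 1.0
            and self.bipolarity_shift == 0.0
        )


# Effects transcribed from the reference findings used by the "reference"
# preset: a positive dependency (deletion lowers polar signal) becomes
# multipliers < 1 on both ends; a negative dependency becomes > 1.
_REFERENCE_EFFECTS: dict[tuple[str, str], dict] = {
    # More Tip1 at the poles of cells lacking Myo52 (negative dependency).
    ("Tip1", "myo52"): dict(mult_end1=1.6, mult_end2=1.6),
    # Tea1 relies on the kinesin Tea2 for polar localisation.
    ("Tea1", "tea2"): dict(mult_end1=0.4, mult_end2=0.4),
    # Tea1 also depends on Tea3, Tea4, Tip1, Mod5, Myo52 and Mal3.
    ("Tea1", "tea3"): dict(mult_end1=0.5, mult_end2=0.5, mult_cyto=0.6),
    ("Tea1", "tea4"): dict(mult_end1=0.5, mult_end2=0.5),
    ("Tea1", "tip1"): dict(mult_end1=0.4, mult_end2=0.4),
    ("Tea1", "mod5"): dict(mult_end1=0.5, mult_end2=0.5),
    ("Tea1", "myo52"): dict(mult_end1=0.6, mult_end2=0.6),
    ("Tea1", "mal3"): dict(mult_end1=0.4, mult_end2=0.4),
    # Microtubule cargo fails to reach the pole without Mal3 or Tip1.
    ("Tea2", "mal3"): dict(mult_end1=0.4, mult_end2=0.4),
    ("Tea4", "mal3"): dict(mult_end1=0.4, mult_end2=0.4),
    ("Tea2", "tip1"): dict(mult_end1=0.4, mult_end2=0.4),
    ("Tea4", "tip1"): dict(mult_end1=0.4, mult_end2=0.4),
    # Myo52 limits accumulation of Tea2/Tea3/Tea4 (proteolysis-like).
    ("Tea2", "myo52"): dict(mult_end1=1.5, mult_end2=1.5, mult_cyto=1.3),
    ("Tea3", "myo52"): dict(mult_end1=1.5, mult_end2=1.5),
    ("Tea4", "myo52"): dict(mult_end1=1.5, mult_end2=1.5),
    # For3 limits Bud6, Mod5, Tea2.
    ("Bud6", "for3"): dict(mult_end1=1.5, mult_end2=1.5),
    ("Mod5", "for3"): dict(mult_end1=1.5, mult_end2=1.5),
    ("Tea2", "for3"): dict(mult_end1=1.5, mult_end2=1.5),
    # NETO shifts within tea1-delta cells (For3, Myo52, Tea2).
    ("For3", "tea1"): dict(bipolarity_shift=-0.25),
    ("Myo52", "tea1"): dict(mult_end1=0.7, mult_end2=0.5,
                            bipolarity_shift=-0.25),
    ("Tea2", "tea1"): dict(bipolarity_shift=-0.25),
    ("Bud6", "tea1"): dict(mult_end1=0.6, mult_end2=0.6),
    ("Myo52", "tea4"): dict(mult_end1=0.6, mult_end2=0.6,
                            bipolarity_shift=-0.2),
}


def build_truth_table(
    design: StudyDesign,
    effect_spec: str | dict | None = "null",
    seed: int | None = None,
) -> list[GroundTruthEffect]:
    """One :class:`GroundTruthEffect` per design combination.

    ``effect_spec`` is either a preset name (``"null"``, ``"reference"``,
    ``"planted"``) or a mapping ``{(marker, deletion): {field: value}}``;
    combinations not covered default to the null effect. ``seed`` only
    matters for the randomised ``"planted"`` preset.
    """
    if effect_spec is None:
        effect_spec = "null"
    if isinstance(effect_spec, str):
        if effect_spec == "null":
            spec_map: dict = {}
        elif effect_spec == "reference":
            spec_map = _REFERENCE_EFFECTS
        elif effect_spec == "planted":
            return planted_truth_table(design, seed=seed)
        else:
            raise ValueError(f"unknown effect preset {effect_spec!r}")
    else:
        spec_map = dict(effect_spec)
        for marker, deletion in spec_map:
            design.check_names(marker, deletion)

    table = []
    for marker, deletion in design.combinations:
        kwargs = spec_map.get((marker, deletion), {})
        table.append(GroundTruthEffect(marker, deletion, **kwargs))
    return table


def planted_truth_table(
    design: StudyDesign,
    n_effects: int = 20,
    low: float = 0.5,
    high: float = 1.6,
    seed: int | None = None,
) -> list[GroundTruthEffect]:
    """Null table with ``n_effects`` strong single-compartment effects.

    Used for parameter-recovery experiments: each planted entry sets one of
    (end1+end2, cytosol) to ``low`` or ``high``. End effects are planted on
    both ends jointly because End1/End2 are assigned per cell by brightness,
    so a single-end multiplier is not identifiable as such downstream.
    """
    rng = np.random.default_rng(seed)
    combos = design.combinations
    if n_effects > 2 * len(combos):
        raise ValueError("more effects requested than available entries")
    # one planted compartment per chosen combination at most
    chosen = rng.choice(len(combos), size=n_effects, replace=False)
    table = {c: GroundTruthEffect(*c) for c in combos}
    planted = []
    for idx in chosen:
        marker, deletion = combos[idx]
        compartment = rng.choice(["ends", "cyto"])
        mult = float(rng.choice([low, high]))
        if compartment == "ends":
            eff = GroundTruthEffect(marker, deletion,
                                    mult_end1=mult, mult_end2=mult)
        else:
            eff = GroundTruthEffect(marker, deletion, mult_cyto=mult)
        table[(marker, deletion)] = eff
        planted.append(eff)
    return [table[c] for c in combos]


def truth_lookup(
    table: list[GroundTruthEffect],
) -> dict[tuple[str, str], GroundTruthEffect]:
    out = {}
    for eff in table:
        key = (eff.marker, eff.deletion)
        if key in out:
            raise ValueError(f"duplicate truth entry for {key}")
        out[key] = eff
    return out
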