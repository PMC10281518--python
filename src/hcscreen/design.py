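"""Screen design and plate-layout construction.

The library arrays one siRNA per well, several independent siRNAs per gene,
across as many multiwell plates as needed.  Under the default control scheme
the two right-most plate columns are reserved for controls: a scrambled
negative-control siRNA in the odd rows of the penultimate column, and two
alternating positive-control siRNAs (targeting a gene whose depletion raises
the readout) filling the last column, alternating by row parity.  Library
siRNAs fill the remaining columns in row-major order; a gene's siRNAs are
placed consecutively.  Leftover positions on the last plate stay empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

from .plates import well_name

CONTROL_SCHEME_COLUMNS_23_24 = "columns_23_24"

NEG_CONTROL_SIRNA = "siNEG.1"
POS_CONTROL_SIRNAS = ("siPOS.2", "siPOS.3")  # odd rows, even rows (1-based)
POS_CONTROL_GENE = "GENE_POS"


@dataclass(frozen=True)
class ScreenDesign:
    """Geometry and size of an arrayed siRNA screen.

    Defaults describe a 521-gene library with three siRNAs per gene, one
    siRNA per well on 16x24 (384-well) plates, two biological replicates,
    and controls confined to the last two plate columns.
    """

    n_genes: int = 521
    sirnas_per_gene: int = 3
    n_replicates: int = 2
    plate_rows: int = 16
    plate_cols: int = 24
    control_scheme: str = CONTROL_SCHEME_COLUMNS_23_24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.sirnas_per_gene < 1:
            raise ValueError("sirnas_per_gene must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.control_scheme != CONTROL_SCHEME_COLUMNS_23_24:
            raise ValueError(f"unknown control scheme {self.control_scheme!r}")
        if self.plate_cols < 3:
            raise ValueError(
                "plate_cols must be >= 3: the last two columns are reserved "
                "for controls, leaving no room for library wells otherwise"
            )
        if self.plate_rows < 1 or self.plate_rows > 26:
            raise ValueError("plate_rows must be in [1, 26]")

    @property
    def n_sirnas(self) -> int:
        return self.n_genes * self.sirnas_per_gene

    @property
    def library_cols(self) -> int:
        """Number of columns available to library siRNAs (all but the two
        control columns)."""
        return self.plate_cols - 2

    @property
    def library_wells_per_plate(self) -> int:
        return self.plate_rows * self.library_cols

    @property
    def n_plates(self) -> int:
        return ceil(self.n_sirnas / self.library_wells_per_plate)

    @property
    def neg_control_col(self) -> int:
        """0-based index of the negative-control column (column 23 on a
        24-column plate)."""
        return self.plate_cols - 2

    @property
    def pos_control_col(self) -> int:
        return self.plate_cols - 1

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def sirna_ids(self, gene_id: str) -> list[str]:
        return [f"{gene_id}.s{k + 1}" for k in range(self.sirnas_per_gene)]


@dataclass(frozen=True)
class WellAssignment:
    """Content of one well: a library siRNA, a control, or nothing."""

    content_class: str  # library | neg_control | pos_control | empty
    sirna_id: str | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.content_class not in ("library", "neg_control", "pos_control", "empty"):
            raise ValueError(f"unknown content_class {self.content_class!r}")
        needs_ids = self.content_class in ("library", "pos_control")
        if needs_ids and (self.sirna_id is None or self.gene_id is None):
            raise ValueError(
                f"{self.content_class} wells need sirna_id and gene_id"
            )
        if self.content_class == "empty" and self.sirna_id is not None:
            raise ValueError("empty wells carry no siRNA")


@dataclass
class PlateLayout:
    """Well -> content map for one plate."""

    plate_id: str
    n_rows: int
    n_cols: int
    wells: dict[str, WellAssignment] = field(default_factory=dict)

    def assignment(self, well: str) -> WellAssignment:
        return self.wells[well]

    def wells_of_class(self, content_class: str) -> list[str]:
        return [w for w, a in self.wells.items() if a.content_class == content_class]


def build_screen_layout(design: ScreenDesign) -> list[PlateLayout]:
    """Lay the library out onto plates under the design's control scheme.

    Library siRNAs fill the non-control columns in row-major order, a gene's
    siRNAs consecutively, spilling over onto further plates as needed.  In
    the negative-control column, odd (1-based) rows carry the scrambled
    control and even rows stay empty; the positive-control column is fully
    occupied, its two siRNA ids alternating with row parity.  The layout is
    the same for every biological replicate.
    """
    sirnas: list[tuple[str, str]] = []
    for gene in design.gene_ids():
        for sid in design.sirna_ids(gene):
            sirnas.append((sid, gene))

    layouts: list[PlateLayout] = []
    idx = 0
    for p in range(design.n_plates):
        plate = PlateLayout(
            plate_id=f"P{p + 1:02d}",
            n_rows=design.plate_rows,
            n_cols=design.plate_cols,
        )
        for r in range(design.plate_rows):
            for c in range(design.plate_cols):
                name = well_name(r, c)
                if c == design.neg_control_col:
                    if r % 2 == 0:  # odd row in 1-based counting
                        plate.wells[name] = WellAssignment("neg_control")
                    else:
                        plate.wells[name] = WellAssignment("empty")
                elif c == design.pos_control_col:
                    sid = POS_CONTROL_SIRNAS[r % 2]
                    plate.wells[name] = WellAssignment(
                        "pos_control", sirna_id=sid, gene_id=POS_CONTROL_GENE
                    )
                else:
                    if idx < len(sirnas):
                        sid, gene = sirnas[idx]
                        plate.wells[name] = WellAssignment(
                            "library", sirna_id=sid, gene_id=gene
                        )
                        idx += 1
                    else:
                        plate.wells[name] = WellAssignment("empty")
        layouts.append(plate)
    if idx != len(sirnas):  # pragma: no cover - guarded by n_plates arithmetic
        raise RuntimeError("library placement did not exhaust the siRNA list")
    return layouts
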