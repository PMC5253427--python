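"""Domain types and file I/O shared by every analysis stage.

The central containers are:

``GenotypeTable``
    individuals x loci diploid allele calls with per-individual metadata
    (coordinates, local population, designatable unit, migratory behaviour,
    covariates).  Every genetic computation reads it.
``DistanceMatrix``
    labelled symmetric pairwise matrix with a ``kind`` tag; the lingua franca
    between modules.
``ResistanceSurface``
    georeferenced raster of positive traversal costs with a no-data mask.
``BarrierSet``
    polyline/polygon features (roads, cutblocks, non-road linear features).

Coordinates are planar metres in one shared projection throughout: the study
region is a single projected area and all geographic distances are Euclidean.
Raster registration: cell ``(r, c)`` has its center at
``(origin_x + (c + 0.5) * cell_size, origin_y + (n_rows - r - 0.5) * cell_size)``
with row 0 the top row.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape

from .errors import ParseError, ValidationError

MISSING = -1  # sentinel for a missing allele slot

BEHAVIOURS = ("migratory", "sedentary", "unclassified")

DISTANCE_KINDS = (
    "genetic_ar",
    "fst",
    "relatedness",
    "euclidean",
    "log_euclidean",
    "lcp",
    "barrier_count",
    "other",
)

# log_euclidean is exempt from the non-negativity check: ln(d) < 0 whenever a
# pair sits closer than one map unit, which is legitimate data.
_NONNEGATIVE_KINDS = {"euclidean", "lcp", "barrier_count"}

BARRIER_CLASSES = ("roads", "cutblocks", "linear_features")


# ---------------------------------------------------------------------------
# GenotypeTable
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Diploid codominant genotypes plus spatial/behavioural metadata.

    ``alleles`` is an ``(n_individuals, n_loci, 2)`` integer array; both slots
    of a locus are either valid allele codes (> 0) or both ``MISSING`` —
    half-calls are rejected at validation.
    """

    individual_ids: list[str]
    population_ids: list[str]
    locus_names: list[str]
    alleles: np.ndarray
    x: np.ndarray
    y: np.ndarray
    du_ids: list[str] | None = None
    behaviours: list[str] | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.individual_ids)
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.du_ids is None:
            self.du_ids = ["DU1"] * n
        if self.behaviours is None:
            self.behaviours = ["unclassified"] * n
        self.validate()

    # -- basic properties ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_ids:
            seen.setdefault(p, None)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean, True where the locus is missing for the individual."""
        return self.alleles[:, :, 0] == MISSING

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        n = len(self.individual_ids)
        if len(set(self.individual_ids)) != n:
            dupes = {i for i in self.individual_ids if self.individual_ids.count(i) > 1}
            raise ValidationError(f"duplicate individual_id(s): {sorted(dupes)}")
        if len(self.population_ids) != n:
            raise ValidationError("population_ids length does not match individuals")
        if n and not self.populations:
            raise ValidationError("population_id set is empty")
        if self.alleles.shape != (n, self.n_loci, 2):
            raise ValidationError(
                f"alleles shape {self.alleles.shape} != ({n}, {self.n_loci}, 2)"
            )
        for lab, arr in (("x", self.x), ("y", self.y)):
            if arr.shape != (n,):
                raise ValidationError(f"coordinate array {lab} has wrong length")
            bad = ~np.isfinite(arr)
            if bad.any():
                who = self.individual_ids[int(np.flatnonzero(bad)[0])]
                raise ValidationError(f"non-finite {lab} coordinate for individual {who!r}")
        for b in self.behaviours or []:
            if b not in BEHAVIOURS:
                raise ValidationError(f"unknown behaviour label {b!r}")
        # half-calls: exactly one slot missing
        half = (self.alleles[:, :, 0] == MISSING) != (self.alleles[:, :, 1] == MISSING)
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValidationError(
                f"half-called genotype for individual {self.individual_ids[int(i)]!r} "
                f"at locus {self.locus_names[int(l)]!r}"
            )
        if self.covariates is not None and len(self.covariates) != n:
            raise ValidationError("covariates row count does not match individuals")

    # -- subsetting ---------------------------------------------------------

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeTable(
            individual_ids=[self.individual_ids[i] for i in idx],
            population_ids=[self.population_ids[i] for i in idx],
            locus_names=list(self.locus_names),
            alleles=self.alleles[idx],
            x=self.x[idx],
            y=self.y[idx],
            du_ids=[self.du_ids[i] for i in idx],
            behaviours=[self.behaviours[i] for i in idx],
            covariates=None
            if self.covariates is None
            else self.covariates.iloc[idx].reset_index(drop=True),
        )

    def filter_behaviour(self, which: str) -> "GenotypeTable":
        """Subset to one behaviour subgroup; ``"all"`` returns the full table."""
        if which == "all":
            return self
        if which not in BEHAVIOURS:
            raise ValidationError(f"unknown behaviour subgroup {which!r}")
        mask = np.array([b == which for b in self.behaviours])
        return self.subset(mask)


# ---------------------------------------------------------------------------
# PopulationAttributes
# ---------------------------------------------------------------------------


@dataclass
class PopulationAttributes:
    """Per-population census size N_c, effective size N_e and range centroid."""

    population_ids: list[str]
    n_census: np.ndarray
    n_effective: np.ndarray
    centroid_x: np.ndarray
    centroid_y: np.ndarray

    def __post_init__(self) -> None:
        self.n_census = np.asarray(self.n_census, dtype=float)
        self.n_effective = np.asarray(self.n_effective, dtype=float)
        self.centroid_x = np.asarray(self.centroid_x, dtype=float)
        self.centroid_y = np.asarray(self.centroid_y, dtype=float)
        k = len(self.population_ids)
        for lab, arr in (
            ("n_census", self.n_census),
            ("n_effective", self.n_effective),
            ("centroid_x", self.centroid_x),
            ("centroid_y", self.centroid_y),
        ):
            if arr.shape != (k,):
                raise ValidationError(f"{lab} length does not match populations")
        if (self.n_census <= 0).any() or (self.n_effective <= 0).any():
            raise ValidationError("population sizes must be positive")
        if not (np.isfinite(self.centroid_x).all() and np.isfinite(self.centroid_y).all()):
            raise ValidationError("population centroids must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population_id": self.population_ids,
                "n_census": self.n_census,
                "n_effective": self.n_effective,
                "centroid_x": self.centroid_x,
                "centroid_y": self.centroid_y,
            }
        )


def read_population_attributes(path) -> PopulationAttributes:
    df = pd.read_csv(path, comment="#")
    required = {"population_id", "n_census", "n_effective", "centroid_x", "centroid_y"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"population attribute file missing columns {sorted(missing)}")
    return PopulationAttributes(
        population_ids=[str(p) for p in df["population_id"]],
        n_census=df["n_census"].to_numpy(),
        n_effective=df["n_effective"].to_numpy(),
        centroid_x=df["centroid_x"].to_numpy(),
        centroid_y=df["centroid_y"].to_numpy(),
    )


def write_population_attributes(attrs: PopulationAttributes, path) -> None:
    attrs.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Labelled symmetric pairwise matrix with a semantic ``kind`` tag.

    ``NaN`` encodes an undefined/missing entry (propagated with pairwise
    deletion by the matrix statistics).  ``diagonal_policy`` is ``"zero"``
    for true distances and ``"undefined"`` (NaN diagonal) for similarity-like
    matrices such as relatedness.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "other"
    diagonal_policy: str = "zero"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("distance matrix labels are not unique")
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if self.kind not in DISTANCE_KINDS:
            raise ValidationError(f"unknown distance kind {self.kind!r}")
        if self.diagonal_policy not in ("zero", "undefined"):
            raise ValidationError(f"unknown diagonal policy {self.diagonal_policy!r}")
        with np.errstate(invalid="ignore"):
            sym = np.allclose(self.values, self.values.T, rtol=1e-8, atol=1e-9, equal_nan=True)
        if not sym:
            raise ValidationError("distance matrix is not symmetric")
        # make symmetry bitwise-exact
        self.values = (self.values + self.values.T) / 2.0
        off = ~np.eye(n, dtype=bool)
        vals = self.values[off]
        finite = vals[np.isfinite(vals)]
        if self.kind in _NONNEGATIVE_KINDS and (finite < 0).any():
            raise ValidationError(f"kind {self.kind!r} requires non-negative distances")
        if self.kind == "relatedness" and ((finite < 0) | (finite > 1)).any():
            raise ValidationError("relatedness values must lie in [0, 1]")
        if self.diagonal_policy == "zero":
            diag = np.diag(self.values)
            if not np.allclose(diag[np.isfinite(diag)], 0.0, atol=1e-12):
                raise ValidationError("diagonal_policy is 'zero' but diagonal is non-zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle (off-diagonal) vectorization, row-major over i > j."""
        iu = np.tril_indices(self.n, k=-1)
        return self.values[iu]

    def align(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Reorder/subset to the given labels."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        try:
            idx = np.array([pos[lab] for lab in labels])
        except KeyError as e:
            raise ValidationError(f"label {e.args[0]!r} not present in matrix") from None
        return DistanceMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
            diagonal_policy=self.diagonal_policy,
        )


def write_matrix(m: DistanceMatrix, path, header_comment: str | None = None) -> None:
    """CSV with a label header row and label first column; >= 17 significant digits."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# kind={m.kind} diagonal_policy={m.diagonal_policy}\n")
        fh.write("," + ",".join(m.labels) + "\n")
        for lab, row in zip(m.labels, m.values):
            fh.write(lab + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path) -> DistanceMatrix:
    kind = "other"
    diagonal_policy = "zero"
    rows: list[list[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("kind="):
                        kind = token.split("=", 1)[1]
                    elif token.startswith("diagonal_policy="):
                        diagonal_policy = token.split("=", 1)[1]
                continue
            rows.append(line.split(","))
    if not rows:
        raise ParseError(f"{path}: empty matrix file")
    labels = rows[0][1:]
    n = len(labels)
    if len(rows) - 1 != n:
        raise ParseError(f"{path}: {len(rows) - 1} data rows for {n} labels")
    values = np.full((n, n), np.nan)
    for i, row in enumerate(rows[1:]):
        if row[0] != labels[i]:
            raise ParseError(
                f"{path}: row label {row[0]!r} does not match column label {labels[i]!r}"
            )
        if len(row) - 1 != n:
            raise ParseError(f"{path}: row {row[0]!r} has {len(row) - 1} values, expected {n}")
        for j, tok in enumerate(row[1:]):
            values[i, j] = float(tok) if tok not in ("", "nan") else np.nan
    with np.errstate(invalid="ignore"):
        if not np.allclose(values, values.T, rtol=0.0, atol=1e-9, equal_nan=True):
            raise ValidationError(f"{path}: matrix on disk is not symmetric")
    return DistanceMatrix(labels=labels, values=values, kind=kind, diagonal_policy=diagonal_policy)


# ---------------------------------------------------------------------------
# ResistanceSurface
# ---------------------------------------------------------------------------


@dataclass
class ResistanceSurface:
    """Raster of positive traversal costs; ``nodata_mask`` True where impassable.

    Registration: row 0 is the TOP row; cell (r, c) center at
    ``(origin_x + (c + .5) * cell_size, origin_y + (n_rows - r - .5) * cell_size)``
    where ``(origin_x, origin_y)`` is the lower-left corner of the grid.
    """

    values: np.ndarray
    cell_size: float
    origin_x: float
    origin_y: float
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("resistance raster must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValidationError("nodata mask shape does not match raster")
        if not self.cell_size > 0:
            raise ValidationError("cell_size must be positive")
        live = self.values[~self.nodata_mask]
        if live.size and (~np.isfinite(live) | (live <= 0)).any():
            raise ValidationError("all unmasked resistance values must be positive and finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Raster cell containing the point (clamped to the grid edge)."""
        c = int(math.floor((x - self.origin_x) / self.cell_size))
        r = self.n_rows - 1 - int(math.floor((y - self.origin_y) / self.cell_size))
        return (min(max(r, 0), self.n_rows - 1), min(max(c, 0), self.n_cols - 1))

    def center_of(self, r: int, c: int) -> tuple[float, float]:
        return (
            self.origin_x + (c + 0.5) * self.cell_size,
            self.origin_y + (self.n_rows - r - 0.5) * self.cell_size,
        )


def read_resistance(path) -> ResistanceSurface:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value)."""
    header: dict[str, float] = {}
    body: list[float] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0].lower()
        if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            if len(parts) != 2:
                raise ParseError(f"{path}: malformed header line {lines[i]!r}")
            header[key] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ParseError(f"{path}: missing header field {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    for line in lines[i:]:
        body.extend(float(tok) for tok in line.split())
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if len(body) != nrows * ncols:
        raise ParseError(
            f"{path}: body has {len(body)} cells, header promises {nrows * ncols}"
        )
    values = np.array(body).reshape(nrows, ncols)
    mask = values == nodata
    bad = ~mask & (values <= 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: non-positive cost {values[r, c]} at cell ({r}, {c}) is not marked NODATA"
        )
    return ResistanceSurface(
        values=np.where(mask, np.nan, values),
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        nodata_mask=mask,
    )


def write_resistance(s: ResistanceSurface, path, nodata: float = -9999.0) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {s.n_cols}\n")
        fh.write(f"nrows {s.n_rows}\n")
        fh.write(f"xllcorner {s.origin_x!r}\n")
        fh.write(f"yllcorner {s.origin_y!r}\n")
        fh.write(f"cellsize {s.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        out = np.where(s.nodata_mask, nodata, s.values)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# BarrierSet
# ---------------------------------------------------------------------------


@dataclass
class BarrierSet:
    """Linear/area features that may impede movement; one feature = one barrier."""

    features: list
    barrier_class: str = "roads"

    def __post_init__(self) -> None:
        if self.barrier_class not in BARRIER_CLASSES:
            raise ValidationError(f"unknown barrier class {self.barrier_class!r}")
        for k, geom in enumerate(self.features):
            if geom.is_empty:
                raise ValidationError(f"barrier feature {k} is empty")
            if not np.isfinite(geom.bounds).all():
                raise ValidationError(f"barrier feature {k} has non-finite coordinates")
            if geom.geom_type == "LineString" and len(geom.coords) < 2:
                raise ValidationError(f"barrier polyline {k} has fewer than 2 vertices")


def read_barriers(path, barrier_class: str = "roads") -> BarrierSet:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ParseError(f"{path}: expected a GeoJSON FeatureCollection")
    feats = []
    for k, f in enumerate(gj.get("features", [])):
        try:
            feats.append(shapely_shape(f["geometry"]))
        except Exception as e:  # malformed geometry
            raise ParseError(f"{path}: feature {k} has invalid geometry: {e}") from None
    props_class = gj.get("barrier_class", barrier_class)
    return BarrierSet(features=feats, barrier_class=props_class)


def write_barriers(b: BarrierSet, path) -> None:
    gj = {
        "type": "FeatureCollection",
        "barrier_class": b.barrier_class,
        "features": [
            {"type": "Feature", "properties": {}, "geometry": shapely_mapping(g)}
            for g in b.features
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


# ---------------------------------------------------------------------------
# Genotype file I/O
# ---------------------------------------------------------------------------


def _parse_genepop_genotype(token: str, line_no: int):
    """Split a concatenated diploid code ('0102', '001002') into two allele ints."""
    if len(token) == 4:
        w = 2
    elif len(token) == 6:
        w = 3
    else:
        raise ParseError(f"line {line_no}: malformed allele code {token!r}")
    if not token.isdigit():
        raise ParseError(f"line {line_no}: malformed allele code {token!r}")
    a1, a2 = int(token[:w]), int(token[w:])
    if (a1 == 0) != (a2 == 0):
        # Genepop allows half-missing on paper but the table type forbids it
        raise ParseError(f"line {line_no}: half-missing genotype {token!r}")
    if a1 == 0:
        return MISSING, MISSING
    return a1, a2


def read_genepop(path) -> GenotypeTable:
    """Parse a Genepop file: title line, locus names, 'pop'-separated blocks."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    if not lines or not lines[0].strip():
        raise ParseError(f"{path}: missing title line")
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        line = lines[i].strip()
        if line:
            # locus names may be one per line or comma-separated on one line
            locus_names.extend(tok.strip() for tok in line.split(",") if tok.strip())
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no 'pop' separator found")
    ids: list[str] = []
    pops: list[str] = []
    alleles: list[list[int]] = []
    pop_no = 0
    for line_no in range(i, len(lines)):
        line = lines[line_no].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_no += 1
            continue
        if "," not in line:
            raise ParseError(f"line {line_no + 1}: expected 'name , genotypes'")
        name, rest = line.split(",", 1)
        toks = rest.split()
        if len(toks) != len(locus_names):
            raise ParseError(
                f"line {line_no + 1}: {len(toks)} genotypes for {len(locus_names)} loci"
            )
        row: list[int] = []
        for tok in toks:
            a1, a2 = _parse_genepop_genotype(tok, line_no + 1)
            row.extend((a1, a2))
        ids.append(name.strip())
        pops.append(f"pop{pop_no}")
        alleles.append(row)
    n = len(ids)
    arr = np.array(alleles, dtype=np.int32).reshape(n, len(locus_names), 2)
    return GenotypeTable(
        individual_ids=ids,
        population_ids=pops,
        locus_names=locus_names,
        alleles=arr,
        x=np.zeros(n),
        y=np.zeros(n),
    )


def write_genepop(g: GenotypeTable, path, title: str = "landgenkit export") -> None:
    width = 3 if int(g.alleles.max(initial=0)) > 99 else 2
    zero = "0" * width
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in g.locus_names:
            fh.write(name + "\n")
        current = None
        order = sorted(range(g.n_individuals), key=lambda i: g.population_ids[i])
        for i in order:
            if g.population_ids[i] != current:
                fh.write("pop\n")
                current = g.population_ids[i]
            codes = []
            for l in range(g.n_loci):
                a1, a2 = g.alleles[i, l]
                if a1 == MISSING:
                    codes.append(zero + zero)
                else:
                    codes.append(f"{a1:0{width}d}{a2:0{width}d}")
            fh.write(f"{g.individual_ids[i]} , " + " ".join(codes) + "\n")


_CSV_META_COLS = ["individual_id", "population_id", "du_id", "behaviour", "x", "y"]


def read_genotypes_csv(path) -> GenotypeTable:
    """CSV dialect: metadata columns, covariates, then ``<locus>_a1``/``<locus>_a2``."""
    df = pd.read_csv(path, comment="#")
    for col in ("individual_id", "population_id", "x", "y"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    locus_names: list[str] = []
    for col in df.columns:
        if col.endswith("_a1"):
            name = col[:-3]
            if f"{name}_a2" not in df.columns:
                raise ParseError(f"{path}: locus {name!r} has _a1 but no _a2 column")
            locus_names.append(name)
    covar_cols = [
        c
        for c in df.columns
        if c not in _CSV_META_COLS and not (c.endswith("_a1") or c.endswith("_a2"))
    ]
    n = len(df)
    alleles = np.full((n, len(locus_names), 2), MISSING, dtype=np.int32)
    for l, name in enumerate(locus_names):
        for s, col in enumerate((f"{name}_a1", f"{name}_a2")):
            vals = pd.to_numeric(df[col], errors="coerce")
            alleles[:, l, s] = np.where(vals.isna(), MISSING, vals.fillna(MISSING)).astype(
                np.int32
            )
    return GenotypeTable(
        individual_ids=[str(v) for v in df["individual_id"]],
        population_ids=[str(v) for v in df["population_id"]],
        locus_names=locus_names,
        alleles=alleles,
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        du_ids=[str(v) for v in df["du_id"]] if "du_id" in df.columns else None,
        behaviours=[str(v) for v in df["behaviour"]] if "behaviour" in df.columns else None,
        covariates=df[covar_cols].reset_index(drop=True) if covar_cols else None,
    )


def write_genotypes_csv(g: GenotypeTable, path) -> None:
    data: dict = {
        "individual_id": g.individual_ids,
        "population_id": g.population_ids,
        "du_id": g.du_ids,
        "behaviour": g.behaviours,
        "x": g.x,
        "y": g.y,
    }
    if g.covariates is not None:
        for col in g.covariates.columns:
            data[col] = g.covariates[col].to_numpy()
    for l, name in enumerate(g.locus_names):
        a1 = g.alleles[:, l, 0].astype(object)
        a2 = g.alleles[:, l, 1].astype(object)
        data[f"{name}_a1"] = [None if v == MISSING else int(v) for v in a1]
        data[f"{name}_a2"] = [None if v == MISSING else int(v) for v in a2]
    pd.DataFrame(data).to_csv(path, index=False)


def read_genotypes(path, format: str = "csv") -> GenotypeTable:
    if format == "genepop":
        return read_genepop(path)
    if format == "csv":
        return read_genotypes_csv(path)
    raise ValidationError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeTable, path, format: str = "csv") -> None:
    if format == "genepop":
        write_genepop(g, path)
    elif format == "csv":
        write_genotypes_csv(g, path)
    else:
        raise ValidationError(f"unknown genotype format {format!r}")
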