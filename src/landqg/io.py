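"""File formats at the package boundary.

GenePop (2- and 3-digit allele dialects, auto-detected) for genotypes; RFC
4180 CSV as the interchange format between pipeline stages; ESRI ASCII grid
for categorical rasters.  Allele codes in GenePop files are preserved as
integers and ``00`` / ``000`` maps to missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from landqg.landscape import LandscapeRaster
from landqg.tables import MISSING, FamilyTraitTable, GenotypeTable

__all__ = [
    "read_genepop",
    "write_genepop",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_traits_csv",
    "write_traits_csv",
    "read_esri_ascii",
    "write_esri_ascii",
    "GenepopParseError",
]


class GenepopParseError(ValueError):
    """Malformed GenePop content, with the offending line number."""

    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def _split_genepop_token(token: str, digits: int, line_no: int) -> tuple[int, int]:
    if len(token) != 2 * digits or not token.isdigit():
        raise GenepopParseError(f"bad allele token {token!r}", line_no)
    a, b = int(token[:digits]), int(token[digits:])
    return (a if a != 0 else MISSING, b if b != 0 else MISSING)


def read_genepop(path) -> GenotypeTable:
    """Read a GenePop file; population blocks become population ids.

    The allele dialect (2- or 3-digit) is auto-detected from the first
    genotype token; mixing token widths within one file is an error.
    Landscape and cohort labels are not part of the format and are filled
    with placeholders (populations are paired consecutively into landscapes).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short for a GenePop header", 1)

    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        entry = lines[i].strip()
        if entry:
            loci.extend(name.strip() for name in entry.split(",") if name.strip())
        i += 1
    if not loci:
        raise GenepopParseError("no locus names before first 'pop'", i)
    if i >= len(lines):
        raise GenepopParseError("no 'pop' block found", len(lines))

    digits: int | None = None
    pop_idx = 0
    records: list[tuple[str, int, list[tuple[int, int]]]] = []
    for line_no in range(i, len(lines)):
        raw = lines[line_no].strip()
        if not raw:
            continue
        if raw.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in raw:
            raise GenepopParseError("genotype line lacks ',' separator", line_no + 1)
        ind_id, rest = raw.split(",", 1)
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"expected {len(loci)} genotypes, found {len(tokens)}", line_no + 1
            )
        widths = {len(t) for t in tokens}
        if len(widths) != 1:
            raise GenepopParseError(f"mixed allele-code widths {sorted(widths)}", line_no + 1)
        width = widths.pop()
        if width not in (4, 6):
            raise GenepopParseError(f"allele token width {width} not 4 or 6", line_no + 1)
        d = width // 2
        if digits is None:
            digits = d
        elif d != digits:
            raise GenepopParseError(
                f"dialect mix: {2 * digits}-digit file has {2 * d}-digit token", line_no + 1
            )
        pairs = [_split_genepop_token(t, d, line_no + 1) for t in tokens]
        records.append((ind_id.strip(), pop_idx, pairs))

    if not records:
        raise GenepopParseError("no genotype records", len(lines))
    alleles = np.array([[list(p) for p in pairs] for _, _, pairs in records], dtype=np.int64)
    meta = pd.DataFrame(
        {
            "individual_id": [r[0] for r in records],
            "population_id": [f"P{r[1]:02d}" for r in records],
            "landscape_id": [f"L{(r[1] - 1) // 2 + 1}" for r in records],
            "cohort": "adult",
        }
    )
    return GenotypeTable(meta, alleles, loci)


def write_genepop(g: GenotypeTable, path, title: str = "landqg export", digits: int = 3) -> None:
    """Write a GenePop file (3-digit dialect by default)."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10**digits
    if (g.alleles >= limit).any():
        raise ValueError(f"allele sizes exceed the {digits}-digit dialect")
    fmt = f"0{digits}d"
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in g.loci:
            fh.write(locus + "\n")
        for pop in g.populations():
            fh.write("pop\n")
            sub = g.subset(population=pop)
            for row in range(sub.n_individuals):
                tokens = []
                for loc in range(sub.n_loci):
                    a, b = sub.alleles[row, loc]
                    a = 0 if a == MISSING else int(a)
                    b = 0 if b == MISSING else int(b)
                    tokens.append(f"{a:{fmt}}{b:{fmt}}")
                fh.write(f"{sub.meta['individual_id'].iloc[row]} , " + " ".join(tokens) + "\n")


def read_genotype_csv(path) -> GenotypeTable:
    return GenotypeTable.from_frame(pd.read_csv(path))


def write_genotype_csv(g: GenotypeTable, path) -> None:
    g.to_frame().to_csv(path, index=False)


def read_traits_csv(path) -> FamilyTraitTable:
    """Read a trait table; accepts wide format or long (trait,value) format."""
    df = pd.read_csv(path)
    if {"trait", "value"}.issubset(df.columns):
        df = (
            df.pivot_table(
                index=FamilyTraitTable.ID_COLUMNS, columns="trait", values="value"
            )
            .reset_index()
            .rename_axis(None, axis=1)
        )
    return FamilyTraitTable(df)


def write_traits_csv(t: FamilyTraitTable, path) -> None:
    t.data.to_csv(path, index=False)


def read_esri_ascii(path, legend: dict[int, str] | None = None) -> LandscapeRaster:
    """Read an ESRI ASCII grid into a :class:`LandscapeRaster`."""
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([int(float(v)) for v in parts])
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII header lacks {key}")
    grid = np.array(rows, dtype=np.int32)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match declared nrows/ncols")
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return LandscapeRaster(
        grid=grid, cell_size=header["cellsize"], origin=origin, legend=legend or {}
    )


def write_esri_ascii(r: LandscapeRaster, path) -> None:
    nrows, ncols = r.grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {r.origin[0]:g}\n")
        fh.write(f"yllcorner {r.origin[1]:g}\n")
        fh.write(f"cellsize {r.cell_size:g}\n")
        fh.write("NODATA_value -9999\n")
        for row in r.grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
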