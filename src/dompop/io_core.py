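"""Core containers and tabular I/O for dominant-marker datasets.

The pipeline's universal substrate is a binary band-presence matrix
(individuals x loci; 1 = band present) together with a sample table mapping
each individual to a population, a habitat class (dune slack vs alkaline
fen), WGS84 coordinates, and an optional replicate linkage. No missing
genotypes are representable: rows with unscored cells are dropped at read
time with a logged count, mirroring the practice of keeping only samples
fully genotyped across all primer combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("dompop")

HABITATS = ("dune", "fen")


class ValidationError(ValueError):
    """Raised when an input artifact violates a structural invariant."""


# ---------------------------------------------------------------------------
# Band matrix
# ---------------------------------------------------------------------------

@dataclass
class BandMatrix:
    """Individuals x loci binary presence/absence with per-locus metadata.

    Parameters
    ----------
    presence : pandas.DataFrame
        Integer 0/1 matrix, index = individual IDs, columns = locus IDs.
    locus_meta : pandas.DataFrame, optional
        Index = locus IDs; columns ``primer_combo`` (label) and ``size_bp``
        (fragment size, bp > 0). Generated metadata is attached when absent.
    """

    presence: pd.DataFrame
    locus_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.presence = self.presence.copy()
        vals = self.presence.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary cell at individual {self.presence.index[i]!r}, "
                f"locus {self.presence.columns[j]!r}: {vals[i, j]!r}")
        if self.presence.index.duplicated().any():
            dups = self.presence.index[self.presence.index.duplicated()].tolist()
            raise ValidationError(f"duplicated individual IDs: {dups}")
        if self.presence.columns.duplicated().any():
            dups = self.presence.columns[self.presence.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated locus IDs: {dups}")
        self.presence = self.presence.astype(np.int8)
        if self.locus_meta is not None:
            meta = self.locus_meta
            missing = set(self.presence.columns) - set(meta.index)
            if missing:
                raise ValidationError(f"locus_meta missing loci: {sorted(missing)[:5]} ...")
            meta = meta.loc[self.presence.columns]
            if (meta["size_bp"].to_numpy() <= 0).any():
                raise ValidationError("fragment_size must be > 0")
            self.locus_meta = meta

    @property
    def individual_ids(self) -> list:
        return list(self.presence.index)

    @property
    def locus_ids(self) -> list:
        return list(self.presence.columns)

    @property
    def n_individuals(self) -> int:
        return self.presence.shape[0]

    @property
    def n_loci(self) -> int:
        return self.presence.shape[1]

    def values(self) -> np.ndarray:
        return self.presence.to_numpy()

    def subset_loci(self, loci) -> "BandMatrix":
        meta = self.locus_meta.loc[list(loci)] if self.locus_meta is not None else None
        return BandMatrix(self.presence[list(loci)], meta)

    def subset_individuals(self, ids) -> "BandMatrix":
        return BandMatrix(self.presence.loc[list(ids)], self.locus_meta)


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["individual_id", "population_id", "habitat", "lon", "lat"]


@dataclass
class SampleTable:
    """Per-individual metadata: population, habitat, coordinates, replicate link."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table.copy()
        missing = [c for c in SAMPLE_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        if "replicate_of" not in t.columns:
            t["replicate_of"] = pd.NA
        if t["individual_id"].duplicated().any():
            dups = t.loc[t["individual_id"].duplicated(), "individual_id"].tolist()
            raise ValidationError(f"duplicated individual IDs in sample table: {dups}")
        bad_hab = sorted(set(t["habitat"]) - set(HABITATS))
        if bad_hab:
            raise ValidationError(f"unknown habitat label(s): {bad_hab}; expected {HABITATS}")
        lat = t["lat"].astype(float)
        lon = t["lon"].astype(float)
        if ((lat < -90) | (lat > 90)).any():
            raise ValidationError("latitude out of [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValidationError("longitude out of [-180, 180]")
        known = set(t["individual_id"])
        reps = t["replicate_of"].dropna()
        unknown_ref = sorted(set(reps) - known)
        if unknown_ref:
            raise ValidationError(f"replicate_of refers to unknown individuals: {unknown_ref}")
        t = t.set_index("individual_id", drop=False)
        t["lat"] = lat.to_numpy()
        t["lon"] = lon.to_numpy()
        self.table = t

    @property
    def individual_ids(self) -> list:
        return list(self.table.index)

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """(original, replicate) ID pairs declared through ``replicate_of``."""
        reps = self.table["replicate_of"].dropna()
        return [(orig, rep_id) for rep_id, orig in reps.items()]


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class PopulationInfo:
    population_id: str
    members: list
    habitat: str
    lon: float   # centroid, decimal degrees
    lat: float


@dataclass
class Dataset:
    """Validated band matrix + sample table + derived population registry."""

    band_matrix: BandMatrix
    samples: SampleTable
    populations: dict[str, PopulationInfo] = field(default_factory=dict)

    def __post_init__(self):
        if not self.populations:
            self.populations = _build_population_registry(self.band_matrix, self.samples)

    # -- convenience accessors ------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.band_matrix.n_individuals

    @property
    def n_loci(self) -> int:
        return self.band_matrix.n_loci

    @property
    def population_ids(self) -> list[str]:
        return list(self.populations)

    def population_of(self) -> pd.Series:
        """individual -> population_id, aligned with the band-matrix rows."""
        return self.samples.table.loc[self.band_matrix.individual_ids, "population_id"]

    def habitat_of_population(self) -> dict[str, str]:
        return {p: info.habitat for p, info in self.populations.items()}

    def population_centroids(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lon": {p: i.lon for p, i in self.populations.items()},
             "lat": {p: i.lat for p, i in self.populations.items()}})

    def drop_replicates(self) -> "Dataset":
        """Dataset without the replicate rows (used by all downstream statistics)."""
        reps = [r for _, r in self.samples.replicate_pairs()]
        if not reps:
            return self
        keep = [i for i in self.band_matrix.individual_ids if i not in set(reps)]
        return self.subset_individuals(keep)

    def subset_individuals(self, ids) -> "Dataset":
        ids = list(ids)
        bm = self.band_matrix.subset_individuals(ids)
        st = self.samples.table.loc[ids].copy()
        kept = set(ids)
        st.loc[~st["replicate_of"].isin(kept), "replicate_of"] = pd.NA
        return Dataset(bm, SampleTable(st.reset_index(drop=True)))

    def subset_loci(self, loci) -> "Dataset":
        return Dataset(self.band_matrix.subset_loci(loci), self.samples,
                       populations=self.populations)

    def subset_populations(self, pops) -> "Dataset":
        pops = set(pops)
        ids = [i for i in self.band_matrix.individual_ids
               if self.samples.table.loc[i, "population_id"] in pops]
        return self.subset_individuals(ids)

    def band_counts(self) -> pd.DataFrame:
        """Populations x loci band-presence counts (replicates excluded)."""
        ds = self.drop_replicates()
        pop = ds.population_of().to_numpy()
        return ds.band_matrix.presence.groupby(pop).sum()

    def population_sizes(self) -> pd.Series:
        ds = self.drop_replicates()
        return ds.population_of().value_counts().sort_index()


def _build_population_registry(bm: BandMatrix, st: SampleTable) -> dict:
    in_bm = set(bm.individual_ids)
    in_st = set(st.individual_ids)
    if in_bm != in_st:
        only_bm = sorted(in_bm - in_st)
        only_st = sorted(in_st - in_bm)
        raise ValidationError(
            "band matrix and sample table individuals differ; "
            f"only in matrix: {only_bm[:10]}; only in samples: {only_st[:10]}")
    t = st.table
    registry: dict[str, PopulationInfo] = {}
    for pop, grp in t.groupby("population_id", sort=True):
        habs = set(grp["habitat"])
        if len(habs) > 1:
            raise ValidationError(f"population {pop!r} mixes habitats {sorted(habs)}")
        registry[str(pop)] = PopulationInfo(
            population_id=str(pop), members=list(grp.index),
            habitat=habs.pop(),
            lon=float(grp["lon"].mean()), lat=float(grp["lat"].mean()))
    for pop, info in registry.items():
        if not info.members:
            raise ValidationError(f"population {pop!r} has no members")
    return registry


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_SEP = {"csv": ",", "tsv": "\t"}


def read_band_matrix(path, dialect: str = "csv",
                     locus_meta_path=None) -> BandMatrix:
    """Read a band matrix (individuals in rows, loci in columns).

    Rows with any unparseable/missing cell are dropped with a logged count
    (no missing genotypes are representable downstream). A value other than
    0/1 in a fully scored row is a hard error naming the offending cell.
    """
    df = pd.read_csv(path, sep=_SEP[dialect], index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    incomplete = numeric.isna().any(axis=1)
    if incomplete.any():
        log.warning("dropping %d incompletely genotyped individuals: %s",
                    incomplete.sum(), list(df.index[incomplete])[:10])
        numeric = numeric.loc[~incomplete]
    meta = None
    if locus_meta_path is not None:
        meta = pd.read_csv(locus_meta_path).set_index("locus_id")
        meta.index = meta.index.astype(str)
    bm = BandMatrix(numeric, meta)
    log.info("read band matrix: %d individuals x %d loci", bm.n_individuals, bm.n_loci)
    return bm


def write_band_matrix(bm: BandMatrix, path, dialect: str = "csv",
                      locus_meta_path=None) -> None:
    bm.presence.to_csv(path, sep=_SEP[dialect], index_label="individual_id")
    if locus_meta_path is not None and bm.locus_meta is not None:
        bm.locus_meta.to_csv(locus_meta_path, index_label="locus_id")


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path)
    df["individual_id"] = df["individual_id"].astype(str)
    df["population_id"] = df["population_id"].astype(str)
    if "replicate_of" in df.columns:
        df["replicate_of"] = df["replicate_of"].astype("string")
    return SampleTable(df)


def write_sample_table(st: SampleTable, path) -> None:
    st.table.reset_index(drop=True).to_csv(path, index=False)


def assemble_dataset(bm: BandMatrix, st: SampleTable) -> Dataset:
    """Join matrix and metadata into a validated :class:`Dataset`.

    Deterministic and independent of input row order: individuals are kept in
    band-matrix order, the population registry is sorted by population ID.
    """
    ds = Dataset(bm, st)
    sizes = ds.population_sizes()
    log.info("assembled dataset: %d individuals, %d loci, %d populations "
             "(sizes %d-%d)", ds.n_individuals, ds.n_loci, len(ds.populations),
             sizes.min(), sizes.max())
    return ds


def read_dataset(band_matrix_path, sample_table_path, locus_meta_path=None,
                 dialect: str = "csv") -> Dataset:
    bm = read_band_matrix(band_matrix_path, dialect, locus_meta_path)
    st = read_sample_table(sample_table_path)
    # samples dropped at matrix read time must be dropped from the table too
    kept = [i for i in st.individual_ids if i in set(bm.individual_ids)]
    if len(kept) != len(st.individual_ids):
        st = SampleTable(st.table.loc[kept].reset_index(drop=True))
    return assemble_dataset(bm, st)
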