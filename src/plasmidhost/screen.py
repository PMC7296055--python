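"""End-to-end screen of one plasmid against a collection of chromosomes.

`PlasmidHostScreen` is the model object: plasmid + chromosomes + metadata.
Its ``fit()`` runs, for each chromosome and each k in {2, 3, 4}: 5-kb
segmentation -> per-segment rho vectors -> (mu, S) Mahalanobis model ->
D^2 of the whole-plasmid rho vector -> empirical P. The Results object
carries the host-prediction table (one row per chromosome) with genus
labels, GC%, length, per-k D^2 / empirical P, and group assignment, plus
ranking (`top_fraction`) and group-comparison methods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import stats as _stats
from .composition import EmptyCompositionError, composition_matrix, rho_vector
from .mahalanobis import DistanceResult, fit_model
from .records import GenomeRecord, gc_content, read_fasta, read_metadata, segment_sequence

__all__ = [
    "MetadataMismatchError",
    "PlasmidHostScreen",
    "ScreenResults",
    "predict_host_similarity",
    "build_table",
    "assign_groups",
    "top_fraction",
]

log = logging.getLogger(__name__)

TAXON_COLUMNS = ("genus", "family", "order", "class", "phylum")


class MetadataMismatchError(KeyError):
    """Genomes present in the FASTA but absent from the metadata table."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(
            f"metadata missing {len(self.missing)} accession(s): "
            + ", ".join(self.missing[:10])
            + ("..." if len(self.missing) > 10 else "")
        )


def predict_host_similarity(
    plasmid: GenomeRecord,
    chromosome: GenomeRecord,
    k: int,
    window_bp: int = 5000,
    strand: str = "given",
) -> DistanceResult:
    """Score one plasmid against one chromosome at one k.

    Returns an NA result (rather than raising) when the chromosome is too
    short for the segment model at this k (n <= 4^k segments).
    """
    segments = segment_sequence(chromosome, window_bp=window_bp)
    try:
        matrix = composition_matrix(segments, k, strand=strand)
    except EmptyCompositionError:
        return DistanceResult(
            source_id=chromosome.id, k=k, d2_plasmid=np.nan,
            segment_d2=np.empty(0), empirical_p=np.nan, na=True,
        )
    model = fit_model(matrix)
    x = rho_vector(plasmid.sequence, k, strand=strand)
    if not x.valid:
        return DistanceResult(
            source_id=chromosome.id, k=k, d2_plasmid=np.nan,
            segment_d2=np.full(matrix.n, np.nan), empirical_p=np.nan, na=True,
            n_segments=matrix.n,
        )
    return model.score(x)


class PlasmidHostScreen:
    """Model: one plasmid against many candidate host chromosomes.

    Parameters
    ----------
    plasmid : GenomeRecord
    genomes : sequence of GenomeRecord
        Candidate host chromosomes. When the metadata carries an
        ``organism`` column, only the largest chromosome per organism is
        retained; rows with a truthy ``exclude`` flag are dropped.
    metadata : DataFrame
        Indexed by accession, with at least a ``genus`` column; must cover
        every genome id.
    ks : iterable of int
        Which k-mer sizes to score (subset of {2, 3, 4}).
    """

    def __init__(
        self,
        plasmid: GenomeRecord,
        genomes: Sequence[GenomeRecord],
        metadata: pd.DataFrame,
        ks: Iterable[int] = (2, 3, 4),
        window_bp: int = 5000,
        strand: str = "given",
        transconjugant_genera: Optional[Set[str]] = None,
    ):
        self.plasmid = plasmid
        self.ks = tuple(sorted(set(int(k) for k in ks)))
        if not self.ks or any(k not in (2, 3, 4) for k in self.ks):
            raise ValueError(f"ks must be a non-empty subset of {{2,3,4}}, got {self.ks}")
        self.window_bp = int(window_bp)
        self.strand = strand
        self.metadata = metadata
        self.transconjugant_genera = (
            set(transconjugant_genera) if transconjugant_genera else None
        )
        missing = [g.id for g in genomes if g.id not in metadata.index]
        if missing:
            raise MetadataMismatchError(missing)
        self.genomes = self._apply_metadata_policies(genomes, metadata)

    @classmethod
    def from_fasta(
        cls,
        plasmid_fasta,
        genomes_fasta,
        metadata_path,
        **kwargs,
    ) -> "PlasmidHostScreen":
        plasmids = read_fasta(plasmid_fasta, role="plasmid")
        if len(plasmids) != 1:
            raise ValueError(
                f"{plasmid_fasta}: expected exactly one plasmid record, "
                f"found {len(plasmids)}"
            )
        paths = [genomes_fasta] if isinstance(genomes_fasta, (str, bytes)) or not isinstance(
            genomes_fasta, (list, tuple)
        ) else list(genomes_fasta)
        genomes: List[GenomeRecord] = []
        for p in paths:
            genomes.extend(read_fasta(p, role="chromosome"))
        ids = [g.id for g in genomes]
        if len(ids) != len(set(ids)):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate genome ids across FASTA inputs: {dups}")
        return cls(plasmids[0], genomes, read_metadata(metadata_path), **kwargs)

    @staticmethod
    def _apply_metadata_policies(
        genomes: Sequence[GenomeRecord], metadata: pd.DataFrame
    ) -> List[GenomeRecord]:
        kept = list(genomes)
        if "exclude" in metadata.columns:
            flags = metadata["exclude"].astype(str).str.lower()
            drop = set(metadata.index[flags.isin({"1", "true", "yes"})])
            kept = [g for g in kept if g.id not in drop]
        if "organism" in metadata.columns:
            best: Dict[str, GenomeRecord] = {}
            order: List[str] = []
            for g in kept:
                org = str(metadata.loc[g.id, "organism"]) or g.id
                if org not in best:
                    order.append(org)
                    best[org] = g
                elif len(g) > len(best[org]):
                    best[org] = g
            kept = [best[o] for o in order]
        return kept

    def fit(self) -> "ScreenResults":
        rows = []
        plasmid_rho = {
            k: rho_vector(self.plasmid.sequence, k, strand=self.strand)
            for k in self.ks
        }
        for genome in self.genomes:
            meta = self.metadata.loc[genome.id]
            row: Dict[str, object] = {"accession": genome.id}
            for col in TAXON_COLUMNS:
                row[col] = str(meta[col]) if col in meta.index else ""
            row["length_bp"] = len(genome)
            row["gc_percent"] = gc_content(genome.sequence)
            segments = segment_sequence(genome, window_bp=self.window_bp)
            for k in self.ks:
                res = self._score_one(segments, plasmid_rho[k], genome.id, k)
                row[f"d2_k{k}"] = res.d2_plasmid
                row[f"p_k{k}"] = res.empirical_p
                row[f"p_k{k}_frac"] = res.p_fraction
            rows.append(row)
        table = pd.DataFrame(rows).set_index("accession", drop=False)
        table = table.sort_index()
        genera = self.transconjugant_genera
        if genera is None and "group" in self.metadata.columns:
            labeled = self.metadata.loc[
                self.metadata["group"] == "Transconjugants", "genus"
            ]
            genera = set(labeled) or None
        if genera:
            table = assign_groups(table, genera)
        else:
            table["group"] = "Unlabeled"
        return ScreenResults(self, table)

    def _score_one(self, segments, plasmid_rho, source_id: str, k: int) -> DistanceResult:
        try:
            matrix = composition_matrix(segments, k, strand=self.strand)
        except EmptyCompositionError:
            return DistanceResult(
                source_id=source_id, k=k, d2_plasmid=np.nan,
                segment_d2=np.empty(0), empirical_p=np.nan, na=True,
            )
        if not plasmid_rho.valid:
            return DistanceResult(
                source_id=source_id, k=k, d2_plasmid=np.nan,
                segment_d2=np.full(matrix.n, np.nan), empirical_p=np.nan,
                na=True, n_segments=matrix.n,
            )
        return fit_model(matrix).score(plasmid_rho)


@dataclass
class ScreenResults:
    """Results of a host-range screen: the per-chromosome prediction table."""

    model: PlasmidHostScreen
    table: pd.DataFrame

    @property
    def ks(self) -> Tuple[int, ...]:
        return self.model.ks

    def na_counts(self) -> Dict[int, int]:
        """Chromosomes with NA distance per k (model unavailable)."""
        return {
            k: int(pd.to_numeric(self.table[f"d2_k{k}"]).isna().sum())
            for k in self.ks
        }

    def assign_groups(self, transconjugant_genera: Set[str]) -> "ScreenResults":
        self.table = assign_groups(self.table, transconjugant_genera)
        return self

    def compare_groups(self, k: int) -> _stats.GroupComparison:
        return _stats.compare_groups(self.table, k)

    def top_fraction(self, fraction: float, policy: str = "any_k", k: Optional[int] = None):
        return top_fraction(self.table, fraction, policy=policy, k=k, ks=self.ks)

    def to_tsv(self, path) -> None:
        """Write the prediction table; NA spelled 'NA', 6 significant digits."""
        cols = ["accession", *TAXON_COLUMNS, "length_bp", "gc_percent"]
        for k in self.ks:
            cols += [f"d2_k{k}", f"p_k{k}", f"p_k{k}_frac"]
        cols.append("group")
        out = self.table[[c for c in cols if c in self.table.columns]]
        out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")

    def summary(self) -> str:
        na = self.na_counts()
        lines = [
            f"Plasmid host-range screen: {self.model.plasmid.id} "
            f"vs {len(self.table)} chromosomes",
            f"  window: {self.model.window_bp} bp, strand: {self.model.strand}",
        ]
        for k in self.ks:
            d2 = pd.to_numeric(self.table[f"d2_k{k}"])
            lines.append(
                f"  k={k}: {int(d2.notna().sum())} scored, {na[k]} NA; "
                f"median D2={d2.median():.6g}"
            )
        counts = self.table["group"].value_counts().to_dict()
        lines.append(f"  groups: {counts}")
        return "\n".join(lines)


def build_table(
    plasmid: GenomeRecord,
    genomes: Sequence[GenomeRecord],
    metadata: pd.DataFrame,
    ks: Iterable[int] = (2, 3, 4),
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper: fitted host-prediction table as a DataFrame."""
    return PlasmidHostScreen(plasmid, genomes, metadata, ks=ks, **kwargs).fit().table


def assign_groups(table: pd.DataFrame, transconjugant_genera: Set[str]) -> pd.DataFrame:
    """Label each row Transconjugants / Others / Unlabeled by genus."""
    if not transconjugant_genera:
        raise ValueError("transconjugant_genera must be non-empty")
    genera = set(transconjugant_genera)
    present = set(table["genus"])
    absent = genera - present
    if absent:
        log.warning(
            "%d transconjugant genera not present in table: %s",
            len(absent), sorted(absent)[:10],
        )
    table = table.copy()
    table["group"] = np.where(
        table["genus"].isin(genera),
        "Transconjugants",
        np.where(table["genus"].astype(str) == "", "Unlabeled", "Others"),
    )
    return table


def top_fraction(
    table: pd.DataFrame,
    fraction: float,
    policy: str = "any_k",
    k: Optional[int] = None,
    ks: Optional[Sequence[int]] = None,
) -> Tuple[pd.DataFrame, Set[str]]:
    """Rows ranking in the smallest-D^2 fraction, and their genera.

    Ranking is over non-NA rows only; the cutoff count is
    ceil(fraction * N_nonNA) per k; ties at the cutoff are broken by
    accession lexicographic order. ``policy="any_k"`` keeps rows qualifying
    at any scored k; ``policy="per_k"`` requires ``k``.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if policy not in ("any_k", "per_k"):
        raise ValueError(f"policy must be 'any_k' or 'per_k', got {policy!r}")
    if ks is None:
        ks = sorted(
            int(c.split("_k")[1]) for c in table.columns
            if c.startswith("d2_k") and not c.endswith("_frac")
        )
    use_ks = [int(k)] if policy == "per_k" else list(ks)
    if policy == "per_k" and k is None:
        raise ValueError("policy='per_k' requires k")
    qualifying = pd.Series(False, index=table.index)
    any_nonna = pd.Series(False, index=table.index)
    for kk in use_ks:
        d2 = pd.to_numeric(table[f"d2_k{kk}"])
        nonna = d2.notna()
        any_nonna |= nonna
        n_nonna = int(nonna.sum())
        if n_nonna == 0:
            continue
        m = math.ceil(fraction * n_nonna)
        acc = table.loc[nonna, "accession"].to_numpy(str)
        d2v = d2[nonna].to_numpy(float)
        order = np.lexsort((acc, d2v))  # d2 ascending, accession breaks ties
        chosen = set(acc[order[:m]])
        qualifying |= table["accession"].isin(chosen)
    if not any_nonna.any():
        raise ValueError("all rows NA: top_fraction undefined")
    rows = table.loc[qualifying]
    return rows, set(rows["genus"])
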