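"""Integrative proteome analyses over an annotated Proteome.

Three reusable operations:

``ptm_enrichment``
    Are residues of a given type (e.g. serine) more often modified (e.g.
    phosphorylated) inside intrinsically disordered regions (IDRs) than in
    folded regions, once the folded comparison set is restricted to
    solvent-accessible residues? Accessibility enters as a per-residue
    values track (relative solvent accessibility in [0, 1]); without the
    accessibility correction the comparison is confounded by burial.

``chemistry_select``
    Percentile-based classification of domains (typically polar low-
    complexity domains) by amino-acid chemistry: keep candidates in the top
    X% by the fraction of an enriched class while in the bottom Y% by the
    summed fraction of depleted classes (defaults: top 20%, bottom 5%).

``abundance_disorder``
    Rank correlation between per-protein disorder fraction and (log)
    protein abundance, plus the correlation between the charge content of a
    protein's IDRs and its abundance, with quantile-binned summaries for
    plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import Domain, Proteome, ResidueClass, resolve_residue_class
from .exceptions import InsufficientDataError
from .tools import (
    domain_coverage_mask,
    fraction_of_class,
    fraction_of_classes,
)

__all__ = [
    "EnrichmentResult",
    "ChemistrySelection",
    "AbundanceDisorderResult",
    "ptm_enrichment",
    "chemistry_select",
    "rk_idr_split",
    "abundance_disorder",
    "tail_percentile_threshold",
]


# ---------------------------------------------------------------------------
# PTM enrichment in IDRs, corrected for solvent accessibility
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Counts and fractions of modified target residues in the IDR stratum
    versus the solvent-accessible folded stratum.

    ``fraction_idr = n_modified_idr / n_target_idr`` and analogously for the
    folded stratum; ``ratio = fraction_idr / fraction_folded_accessible``.
    A fraction whose denominator is zero is ``None`` (undefined), as is the
    ratio when the folded fraction is zero or undefined. ``pvalue`` is a
    two-proportion z-test of the two fractions (``None`` when either stratum
    is degenerate).
    """

    site_type: str
    target_residue: str
    accessibility_threshold: float
    n_target_idr: int = 0
    n_modified_idr: int = 0
    n_target_folded_accessible: int = 0
    n_modified_folded_accessible: int = 0
    n_proteins: int = 0
    n_skipped_proteins: int = 0

    @property
    def fraction_idr(self) -> Optional[float]:
        if self.n_target_idr == 0:
            return None
        return self.n_modified_idr / self.n_target_idr

    @property
    def fraction_folded_accessible(self) -> Optional[float]:
        if self.n_target_folded_accessible == 0:
            return None
        return self.n_modified_folded_accessible / self.n_target_folded_accessible

    @property
    def ratio(self) -> Optional[float]:
        f_idr = self.fraction_idr
        f_folded = self.fraction_folded_accessible
        if f_idr is None or f_folded is None or f_folded == 0:
            return None
        return f_idr / f_folded

    @property
    def pvalue(self) -> Optional[float]:
        if self.n_target_idr == 0 or self.n_target_folded_accessible == 0:
            return None
        from statsmodels.stats.proportion import proportions_ztest

        counts = np.array([self.n_modified_idr, self.n_modified_folded_accessible])
        nobs = np.array([self.n_target_idr, self.n_target_folded_accessible])
        if counts.sum() in (0, nobs.sum()):
            return None  # zero pooled variance
        stat, p = proportions_ztest(counts, nobs)
        return float(p)

    def to_frame(self) -> pd.DataFrame:
        """One-row summary table (TSV-friendly)."""
        return pd.DataFrame(
            [{
                "site_type": self.site_type,
                "target_residue": self.target_residue,
                "accessibility_threshold": self.accessibility_threshold,
                "n_target_idr": self.n_target_idr,
                "n_modified_idr": self.n_modified_idr,
                "n_target_folded_accessible": self.n_target_folded_accessible,
                "n_modified_folded_accessible": self.n_modified_folded_accessible,
                "fraction_idr": self.fraction_idr,
                "fraction_folded_accessible": self.fraction_folded_accessible,
                "ratio": self.ratio,
                "pvalue": self.pvalue,
                "n_proteins": self.n_proteins,
                "n_skipped_proteins": self.n_skipped_proteins,
            }]
        )


def ptm_enrichment(
    proteome: Proteome,
    site_type: str,
    target_residue: str,
    idr_domain_type: str = "IDR",
    accessibility_track: str = "accessibility",
    accessibility_threshold: float = 0.25,
    filter_idr_by_accessibility: bool = False,
) -> EnrichmentResult:
    """Modification fraction of a target residue in IDRs versus
    solvent-accessible folded regions.

    Every residue equal to ``target_residue`` is classified as IDR (covered
    by any domain of ``idr_domain_type``) or folded. Folded residues enter
    the denominator only when their accessibility-track value is >= the
    threshold; IDR residues are not accessibility-filtered by default, since
    disordered regions lack a fixed structure for the accessibility estimate
    to describe (set ``filter_idr_by_accessibility=True`` to filter both
    strata). A residue counts as modified when any site of ``site_type``
    sits at its position. Proteins lacking the accessibility track are
    skipped and tallied in ``n_skipped_proteins``.
    """
    result = EnrichmentResult(
        site_type=site_type,
        target_residue=target_residue.upper(),
        accessibility_threshold=float(accessibility_threshold),
    )
    target = target_residue.upper()
    for protein in proteome:
        if not protein.has_track(accessibility_track):
            result.n_skipped_proteins += 1
            continue
        result.n_proteins += 1
        seq = np.frombuffer(protein.sequence.encode("ascii"), dtype=np.uint8)
        is_target = seq == ord(target)
        if not is_target.any():
            continue
        in_idr = domain_coverage_mask(protein, idr_domain_type)
        acc = np.asarray(protein.track(accessibility_track).values, dtype=float)
        accessible = acc >= accessibility_threshold
        modified = np.zeros(len(protein), dtype=bool)
        for pos in protein.site_positions(site_type):
            modified[pos - 1] = True

        idr_targets = is_target & in_idr
        if filter_idr_by_accessibility:
            idr_targets &= accessible
        folded_targets = is_target & ~in_idr & accessible

        result.n_target_idr += int(idr_targets.sum())
        result.n_modified_idr += int((idr_targets & modified).sum())
        result.n_target_folded_accessible += int(folded_targets.sum())
        result.n_modified_folded_accessible += int((folded_targets & modified).sum())
    return result


# ---------------------------------------------------------------------------
# percentile-based chemistry classification of domains
# ---------------------------------------------------------------------------

def tail_percentile_threshold(
    values: Sequence[float], percentile: float, tail: str
) -> float:
    """Nearest-rank threshold delimiting a tail of the sample.

    For ``tail="upper"`` the threshold is the k-th largest value with
    ``k = ceil(percentile / 100 * n)`` (clipped to [1, n]): the values >= it
    form the top ``percentile`` percent, ties included. For
    ``tail="lower"`` it is the k-th smallest value, and values <= it form
    the bottom tail. ``percentile=100`` therefore admits every value and
    ``percentile=0`` only the tied extreme set.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    k = math.ceil(percentile / 100.0 * n)
    k = min(max(k, 1), n)
    if tail == "upper":
        return float(arr[n - k])
    if tail == "lower":
        return float(arr[k - 1])
    raise ValueError("tail must be 'upper' or 'lower'")


@dataclass
class ChemistrySelection:
    """Domains passing a top-X% enrichment / bottom-Y% depletion double cut.

    ``selected`` holds ``(unique_id, Domain)`` pairs in deterministic
    proteome order. The per-candidate fractions and thresholds used for the
    cut are retained so the selection is auditable.
    """

    selected: List[Tuple[str, Domain]]
    enrich_class: ResidueClass
    deplete_classes: List[ResidueClass]
    enrich_percentile: float
    deplete_percentile: float
    candidate_count: int
    enrich_threshold: Optional[float] = None
    deplete_threshold: Optional[float] = None
    warnings: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.selected)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for uid, dom in self.selected:
            rows.append({
                "unique_ID": uid,
                "start": dom.start,
                "stop": dom.stop,
                "domain_type": dom.domain_type,
                "enrich_fraction": fraction_of_class(dom, self.enrich_class),
                "deplete_fraction": fraction_of_classes(dom, self.deplete_classes)
                if self.deplete_classes else 0.0,
            })
        return pd.DataFrame(
            rows,
            columns=["unique_ID", "start", "stop", "domain_type",
                     "enrich_fraction", "deplete_fraction"],
        )


def chemistry_select(
    proteome: Proteome,
    candidate_domain_type: str,
    enrich_class: Union[str, ResidueClass, Iterable[str]],
    deplete_classes: Sequence[Union[str, ResidueClass, Iterable[str]]] = (),
    enrich_percentile: float = 20.0,
    deplete_percentile: float = 5.0,
    min_length: int = 30,
) -> ChemistrySelection:
    """Select domains in the top ``enrich_percentile`` % by one chemistry and
    the bottom ``deplete_percentile`` % by the summed depleted chemistries.

    Candidates are all domains of ``candidate_domain_type`` with length >=
    ``min_length``. Thresholds are empirical nearest-rank percentiles over
    the candidates themselves; comparisons are inclusive, so ties at a
    threshold are kept. Fewer than 20 candidates attaches a
    percentile-instability warning; zero candidates yields an empty
    selection.
    """
    enrich_cls = resolve_residue_class(enrich_class)
    deplete_cls = [resolve_residue_class(c) for c in deplete_classes]

    candidates: List[Tuple[str, Domain]] = []
    for protein in proteome:
        for dom in protein.get_domains_by_type(candidate_domain_type):
            if len(dom) >= min_length:
                candidates.append((protein.unique_id, dom))

    selection = ChemistrySelection(
        selected=[],
        enrich_class=enrich_cls,
        deplete_classes=deplete_cls,
        enrich_percentile=float(enrich_percentile),
        deplete_percentile=float(deplete_percentile),
        candidate_count=len(candidates),
    )
    if not candidates:
        return selection
    if len(candidates) < 20:
        selection.warnings.append(
            f"only {len(candidates)} candidates; empirical percentile "
            "thresholds are unstable below ~20"
        )

    enrich_fracs = np.array([fraction_of_class(d, enrich_cls) for _, d in candidates])
    if deplete_cls:
        deplete_fracs = np.array(
            [fraction_of_classes(d, deplete_cls) for _, d in candidates]
        )
    else:
        deplete_fracs = np.zeros(len(candidates))

    enrich_thr = tail_percentile_threshold(enrich_fracs, enrich_percentile, "upper")
    deplete_thr = tail_percentile_threshold(deplete_fracs, deplete_percentile, "lower")
    selection.enrich_threshold = enrich_thr
    selection.deplete_threshold = deplete_thr

    for (uid, dom), fe, fd in zip(candidates, enrich_fracs, deplete_fracs):
        if fe >= enrich_thr and fd <= deplete_thr:
            selection.selected.append((uid, dom))
    return selection


def rk_idr_split(
    proteome: Proteome,
    idr_domain_type: str = "IDR",
    enrich_percentile: float = 20.0,
    deplete_percentile: float = 100.0,
    min_length: int = 30,
) -> Tuple[ChemistrySelection, ChemistrySelection]:
    """Split IDRs into arginine-enriched and lysine-enriched candidate lists.

    A thin specialization of :func:`chemistry_select` with the single-residue
    classes {R} and {K}: the first returned selection is the top
    ``enrich_percentile`` % of IDRs by arginine fraction, the second by
    lysine fraction. By default no depletion filter is applied
    (``deplete_percentile=100``); lowering it additionally requires the
    opposite residue to be depleted, and under permissive thresholds one IDR
    may appear in both lists.
    """
    arg = chemistry_select(
        proteome, idr_domain_type,
        enrich_class=ResidueClass("arginine", "R"),
        deplete_classes=[ResidueClass("lysine", "K")],
        enrich_percentile=enrich_percentile,
        deplete_percentile=deplete_percentile,
        min_length=min_length,
    )
    lys = chemistry_select(
        proteome, idr_domain_type,
        enrich_class=ResidueClass("lysine", "K"),
        deplete_classes=[ResidueClass("arginine", "R")],
        enrich_percentile=enrich_percentile,
        deplete_percentile=deplete_percentile,
        min_length=min_length,
    )
    return arg, lys


# ---------------------------------------------------------------------------
# disorder versus abundance
# ---------------------------------------------------------------------------

@dataclass
class AbundanceDisorderResult:
    """Rank correlations of disorder content and IDR charge with abundance.

    ``disorder_correlation`` is the Spearman correlation between per-protein
    disorder fraction and log10 abundance over all usable proteins;
    ``charge_correlation`` is the same statistic for the length-weighted
    charged-residue fraction of each protein's IDRs, over proteins carrying
    at least one IDR. A correlation is ``None`` (flagged in ``flags``) when
    either variable has zero rank variance. ``binned`` partitions proteins
    into abundance quantile bins with the mean of each quantity per bin.
    """

    n_proteins: int
    n_skipped: int
    n_proteins_with_idr: int
    disorder_correlation: Optional[float]
    disorder_pvalue: Optional[float]
    charge_correlation: Optional[float]
    charge_pvalue: Optional[float]
    binned: pd.DataFrame
    flags: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "n_proteins": self.n_proteins,
                "n_skipped": self.n_skipped,
                "n_proteins_with_idr": self.n_proteins_with_idr,
                "disorder_correlation": self.disorder_correlation,
                "disorder_pvalue": self.disorder_pvalue,
                "charge_correlation": self.charge_correlation,
                "charge_pvalue": self.charge_pvalue,
            }]
        )


def _spearman(x: np.ndarray, y: np.ndarray) -> Tuple[Optional[float], Optional[float]]:
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return None, None
    rho, p = stats.spearmanr(x, y)
    if np.isnan(rho):
        return None, None
    return float(rho), float(p)


def abundance_disorder(
    proteome: Proteome,
    abundance_attribute_key: str = "abundance",
    idr_domain_type: str = "IDR",
    log_transform: bool = True,
    n_bins: int = 5,
    charged_class: Union[str, ResidueClass] = "charged",
) -> AbundanceDisorderResult:
    """Correlate per-protein disorder fraction (and IDR charge content) with
    protein abundance.

    Abundance is read from the named protein attribute; proteins lacking it,
    or with a non-positive or unparseable value, are skipped and tallied.
    ``log_transform`` takes log10 of abundance before binning (the headline
    statistics are rank-based, hence invariant to any strictly monotone
    transform). Fewer than 3 usable proteins raises
    :class:`InsufficientDataError`.
    """
    charged = resolve_residue_class(charged_class)
    rows = []
    n_skipped = 0
    for protein in proteome:
        raw = protein.attributes.get(abundance_attribute_key)
        if raw is None:
            n_skipped += 1
            continue
        try:
            abundance = float(raw)
        except ValueError:
            n_skipped += 1
            continue
        if abundance <= 0 or not math.isfinite(abundance):
            n_skipped += 1
            continue
        idrs = protein.get_domains_by_type(idr_domain_type)
        covered = int(domain_coverage_mask(protein, idr_domain_type).sum())
        disorder = covered / len(protein)
        if idrs:
            total_len = sum(len(d) for d in idrs)
            charge = sum(
                fraction_of_class(d, charged) * len(d) for d in idrs
            ) / total_len
        else:
            charge = np.nan
        rows.append((protein.unique_id, abundance, disorder, charge))

    if len(rows) < 3:
        raise InsufficientDataError(
            f"only {len(rows)} proteins with usable '{abundance_attribute_key}' "
            "attribute (need >= 3)"
        )

    df = pd.DataFrame(rows, columns=["unique_ID", "abundance", "disorder_fraction",
                                     "idr_charged_fraction"])
    x = np.log10(df["abundance"].to_numpy()) if log_transform \
        else df["abundance"].to_numpy()
    df["log10_abundance" if log_transform else "abundance_scale"] = x

    flags = []
    rho_d, p_d = _spearman(x, df["disorder_fraction"].to_numpy())
    if rho_d is None:
        flags.append("disorder correlation undefined (zero rank variance)")

    with_idr = df.dropna(subset=["idr_charged_fraction"])
    if len(with_idr) >= 3:
        rho_c, p_c = _spearman(
            with_idr["log10_abundance" if log_transform else "abundance_scale"].to_numpy(),
            with_idr["idr_charged_fraction"].to_numpy(),
        )
    else:
        rho_c, p_c = None, None
    if rho_c is None:
        flags.append("IDR charge correlation undefined")

    # abundance quantile bins (rank-based, so the bins partition the ranked
    # proteins even with heavy ties)
    ranks = stats.rankdata(x, method="average")
    bins = min(n_bins, len(df))
    df["abundance_bin"] = pd.qcut(ranks, q=bins, labels=False, duplicates="drop")
    binned = (
        df.groupby("abundance_bin", observed=True)
        .agg(
            n=("unique_ID", "size"),
            mean_abundance=("abundance", "mean"),
            mean_disorder_fraction=("disorder_fraction", "mean"),
            mean_idr_charged_fraction=("idr_charged_fraction", "mean"),
        )
        .reset_index()
    )

    return AbundanceDisorderResult(
        n_proteins=len(df),
        n_skipped=n_skipped,
        n_proteins_with_idr=len(with_idr),
        disorder_correlation=rho_d,
        disorder_pvalue=p_d,
        charge_correlation=rho_c,
        charge_pvalue=p_c,
        binned=binned,
        flags=flags,
    )
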