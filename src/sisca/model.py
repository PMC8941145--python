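"""High-level modelling interface: build a `SiscaModel` from identifications
and peak lists, call :meth:`SiscaModel.fit`, and read everything off the
returned :class:`SiscaResults` — per-peptide R² profiles, per-MAG
trajectories with point-estimate RIAs and labeled fractions, the PCA
ordination with cluster ellipses, lifestyle calls, growth estimates and the
community carbon-replacement summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .chem import RIAGrid, reference_pattern_set, predict_pattern
from .constants import NATURAL_13C
from .core import (
    LifestyleThresholds,
    MAGTrajectory,
    OrdinationResult,
    RIAProfile,
    aggregate_profiles,
    classify_lifestyle,
    ordinate,
    overlap_verdicts,
    ria_profile,
    validate_clusters,
)
from .extraction import (
    MeasuredPattern,
    PeakList,
    PeptideIdentification,
    Rejection,
    filter_peptides,
    locate_pattern,
    require_replicates,
    validate_pattern,
)
from .growth import (
    GrowthEstimate,
    LabelingSummary,
    aggregate_growth,
    biomass_label_fraction,
    decompose_intensities,
    doublings,
    generation_time,
    most_probable_ria,
)

__all__ = ["SiscaModel", "SiscaResults"]


class SiscaModel:
    """Stable Isotope Cluster Analysis of a protein-SIP experiment.

    Parameters
    ----------
    identifications
        Peptide identifications from the ¹²C reference samples.
    peak_lists
        sample id -> centroid peak list of the matching ¹³C sample.
    mag_map
        protein accession -> (MAG id, genus); used to resolve peptide
        uniqueness.  Omit (``None``) if identifications already carry a
        resolved ``label`` and should not be re-filtered.
    grid
        RIA grid for reference patterns (default 0–100 % in 5 % steps).
    ppm_tol, rt_tol_min
        Matching gates for pattern location (defaults 10 ppm, 3 min).
    min_replicates
        Minimum replicate support per MAG/time point (default 2).
    timepoint_days
        time-point label -> incubation days, for generation times.
    """

    def __init__(
        self,
        identifications: Sequence[PeptideIdentification],
        peak_lists: Mapping[str, PeakList],
        mag_map: Mapping[str, tuple[str, str]] | None = None,
        grid: RIAGrid | None = None,
        ppm_tol: float = 10.0,
        rt_tol_min: float = 3.0,
        m1_rel_threshold: float = 0.05,
        min_replicates: int = 2,
        timepoint_days: Mapping[str, float] | None = None,
        eq1_convention: str = "as-printed",
    ):
        self.identifications = list(identifications)
        self.peak_lists = dict(peak_lists)
        self.mag_map = dict(mag_map) if mag_map is not None else None
        self.grid = grid or RIAGrid.default()
        self.ppm_tol = ppm_tol
        self.rt_tol_min = rt_tol_min
        self.m1_rel_threshold = m1_rel_threshold
        self.min_replicates = min_replicates
        self.timepoint_days = dict(timepoint_days or {})
        self.eq1_convention = eq1_convention

    @classmethod
    def from_simulation(cls, dataset, **kwargs) -> "SiscaModel":
        """Build directly from a :class:`~sisca.simulate.SimulatedDataset`."""
        kwargs.setdefault("timepoint_days", dict(dataset.spec.timepoints))
        return cls(
            identifications=dataset.identifications,
            peak_lists=dataset.peak_lists,
            mag_map=dataset.mag_map(),
            **kwargs,
        )

    @classmethod
    def from_files(
        cls,
        identifications_path,
        peak_dir,
        fasta_path=None,
        **kwargs,
    ) -> "SiscaModel":
        from pathlib import Path

        from .io import read_identifications, read_mag_map, read_peak_list

        idents = read_identifications(identifications_path)
        peaks = {
            p.stem: read_peak_list(p) for p in sorted(Path(peak_dir).glob("*.tsv"))
        }
        mag_map = read_mag_map(fasta_path) if fasta_path else None
        return cls(idents, peaks, mag_map, **kwargs)

    # -- fitting --------------------------------------------------------

    def fit(
        self,
        validate: bool = True,
        cluster_labels: Mapping[str, str] | None = None,
        confidence: float = 0.95,
        lifestyle_thresholds: LifestyleThresholds | None = None,
        layout: str = "per-mag",
    ) -> "SiscaResults":
        """Run the full analysis and return a results object.

        Stages: uniqueness filtering → pattern location → M−1/overlap
        validation → replicate gating → R² profiling on the RIA grid →
        per-MAG aggregation → ordination (+ cluster ellipses when labels are
        given, else Ward clusters into one group per lifestyle candidate are
        *not* invented — clustering stays analyst-controlled) → lifestyle
        classification from point-estimate RIA trajectories → growth and
        community-labeling summaries.
        """
        idents = (
            filter_peptides(self.identifications, self.mag_map)
            if self.mag_map is not None
            else list(self.identifications)
        )
        located: list[MeasuredPattern] = []
        rejections: list[Rejection] = []
        by_sample: dict[str, list[PeptideIdentification]] = {}
        for ident in idents:
            by_sample.setdefault(ident.sample, []).append(ident)
        for sample, members in sorted(by_sample.items()):
            peaks = self.peak_lists.get(sample)
            if peaks is None:
                continue
            found = [
                m
                for ident in members
                if (
                    m := locate_pattern(
                        ident, peaks, self.ppm_tol, self.rt_tol_min
                    )
                )
                is not None
            ]
            if validate:
                for m in found:
                    verdict = validate_pattern(
                        m,
                        neighbors=found,
                        m1_rel_threshold=self.m1_rel_threshold,
                        ppm_tol=self.ppm_tol,
                        rt_tol=self.rt_tol_min,
                    )
                    if isinstance(verdict, Rejection):
                        rejections.append(verdict)
                    else:
                        located.append(verdict)
            else:
                located.extend(found)
        accepted = require_replicates(located, self.min_replicates)

        # R² profiles against cached per-peptide reference sets
        ref_cache: dict[tuple[str, int], list] = {}
        profiles: list[RIAProfile] = []
        growth_rows: list[GrowthEstimate] = []
        peptide_records: list[dict] = []
        for m in accepted:
            ident = m.identification
            key = (ident.sequence, ident.charge)
            if key not in ref_cache:
                ref_cache[key] = reference_pattern_set(
                    ident.composition(), ident.charge, self.grid
                )
            refs = ref_cache[key]
            prof = ria_profile(
                m.pattern, refs, self.grid,
                owner=ident.label or (ident.mags[0] if ident.mags else ""),
                timepoint=ident.timepoint,
            )
            profiles.append(prof)
            ria, ria_flags = most_probable_ria(prof)
            natural = predict_pattern(ident.composition(), NATURAL_13C, ident.charge)
            i_u, i_l, dflags = decompose_intensities(m.pattern, natural)
            n = doublings(i_u, i_l, self.eq1_convention)
            dt = self.timepoint_days.get(ident.timepoint, float("nan"))
            # n below numerical noise means no quantifiable doubling signal
            quantifiable = n is not None and n > 1e-6 and dt == dt
            t_d = generation_time(n, dt) if quantifiable else None
            growth_rows.append(
                GrowthEstimate(
                    owner=prof.owner,
                    i_unlabeled=i_u,
                    i_labeled=i_l,
                    n=n,
                    t_d=t_d,
                    dt_days=dt,
                    convention=self.eq1_convention,
                    flags=ria_flags | dflags,
                )
            )
            peptide_records.append(
                {
                    "peptide": ident.sequence,
                    "charge": ident.charge,
                    "owner": prof.owner,
                    "timepoint": ident.timepoint,
                    "replicate": ident.replicate,
                    "ria": ria,
                    "i_unlabeled": i_u,
                    "i_labeled": i_l,
                    "labeled_fraction": i_l / (i_u + i_l) if i_u + i_l > 0 else 0.0,
                }
            )

        aggregated = aggregate_profiles(profiles) if profiles else []
        peptide_table = pd.DataFrame(peptide_records)

        trajectories = self._build_trajectories(aggregated, peptide_table)
        ordination = None
        overlaps: dict = {}
        if len(trajectories) >= 3:
            ordination = ordinate(trajectories, layout=layout)
            if cluster_labels:
                ordination = validate_clusters(ordination, cluster_labels, confidence)
                overlaps = overlap_verdicts(ordination)
        lifestyles = {
            t.mag_id: classify_lifestyle(t, lifestyle_thresholds)
            for t in trajectories
            if len(t.ria) >= 2
        }

        labeling = {}
        if not peptide_table.empty:
            for tp, sub in peptide_table.groupby("timepoint"):
                labeling[tp] = biomass_label_fraction(
                    [
                        (row.owner, row.i_unlabeled, row.i_labeled, row.ria)
                        for row in sub.itertuples(index=False)
                    ],
                    timepoint=tp,
                )

        return SiscaResults(
            model=self,
            profiles=profiles,
            aggregated_profiles=aggregated,
            trajectories=trajectories,
            ordination=ordination,
            cluster_overlaps=overlaps,
            lifestyles=lifestyles,
            growth_estimates=growth_rows,
            growth_by_mag=aggregate_growth(growth_rows),
            labeling=labeling,
            peptide_table=peptide_table,
            rejections=rejections,
            n_located=len(located),
            n_accepted=len(accepted),
        )

    def _build_trajectories(
        self, aggregated: Sequence[RIAProfile], peptide_table: pd.DataFrame
    ) -> list[MAGTrajectory]:
        ordered_tp = sorted(
            {p.timepoint for p in aggregated},
            key=lambda tp: self.timepoint_days.get(tp, float("inf")),
        ) if aggregated else []
        by_mag: dict[str, dict[str, RIAProfile]] = {}
        for p in aggregated:
            by_mag.setdefault(p.owner, {})[p.timepoint] = p
        trajectories = []
        for mag in sorted(by_mag):
            tps = [tp for tp in ordered_tp if tp in by_mag[mag]]
            profs = tuple(by_mag[mag][tp] for tp in tps)
            rias = tuple(most_probable_ria(p)[0] for p in profs)
            fracs = []
            for tp in tps:
                sub = peptide_table[
                    (peptide_table.owner == mag) & (peptide_table.timepoint == tp)
                ]
                fracs.append(float(sub.labeled_fraction.mean()) if len(sub) else 0.0)
            trajectories.append(
                MAGTrajectory(
                    mag_id=mag,
                    timepoints=tuple(tps),
                    profiles=profs,
                    ria=rias,
                    labeled_fraction=tuple(fracs),
                )
            )
        return trajectories


@dataclass
class SiscaResults:
    """Everything a fitted :class:`SiscaModel` computed."""

    model: SiscaModel
    profiles: list[RIAProfile]
    aggregated_profiles: list[RIAProfile]
    trajectories: list[MAGTrajectory]
    ordination: OrdinationResult | None
    cluster_overlaps: dict
    lifestyles: dict[str, tuple[str, str]]
    growth_estimates: list[GrowthEstimate]
    growth_by_mag: dict[str, dict]
    labeling: dict[str, LabelingSummary]
    peptide_table: pd.DataFrame
    rejections: list
    n_located: int
    n_accepted: int

    def trajectory(self, mag_id: str) -> MAGTrajectory:
        for t in self.trajectories:
            if t.mag_id == mag_id:
                return t
        raise KeyError(mag_id)

    def summary(self) -> str:
        """Human-readable overview of the fit."""
        lines = [
            "Stable Isotope Cluster Analysis",
            "=" * 47,
            f"peptide patterns located:   {self.n_located}",
            f"accepted after replicates:  {self.n_accepted}",
            f"rejected (M-1/overlap):     {len(self.rejections)}",
            f"MAG/genus groups:           {len(self.trajectories)}",
            f"Eq. 1 convention:           {self.model.eq1_convention}",
            "",
            f"{'MAG':<28}{'RIA trajectory':<24}{'lifestyle':<28}t_d",
        ]
        for t in self.trajectories:
            ria_str = " ".join(f"{r:.2f}" for r in t.ria)
            label = self.lifestyles.get(t.mag_id, ("-",))[0]
            growth = self.growth_by_mag.get(t.mag_id, {})
            if growth.get("quantifiable"):
                td = f"{growth['t_d_mean']:.1f}±{growth['t_d_sd']:.1f} d"
            else:
                td = "na"
            lines.append(f"{t.mag_id:<28}{ria_str:<24}{label:<28}{td}")
        if self.labeling:
            lines.append("")
            lines.append("community 13C carbon fraction:")
            for tp in sorted(
                self.labeling, key=lambda x: self.model.timepoint_days.get(x, 0)
            ):
                s = self.labeling[tp]
                lines.append(
                    f"  {tp}: {100 * s.fraction_13c:.1f}%  "
                    f"({s.n_peptides} peptides, {s.weighting})"
                )
        if self.ordination is not None and self.ordination.ellipses:
            n_overlap = sum(self.cluster_overlaps.values())
            lines.append("")
            lines.append(
                f"clusters: {len(self.ordination.ellipses)} ellipses at 95% "
                f"confidence, {n_overlap} overlapping pair(s)"
            )
        return "\n".join(lines)

    def plot_ordination(self, ax=None, annotate: bool = True):
        """PC1/PC2 scatter with cluster confidence ellipses (matplotlib)."""
        import matplotlib.pyplot as plt

        if self.ordination is None:
            raise ValueError("no ordination available (need >= 3 MAGs)")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        ordn = self.ordination
        labels = ordn.cluster_labels or {m: "" for m in ordn.mag_ids}
        clusters = sorted(set(labels.values()))
        cmap = plt.get_cmap("tab10")
        colors = {c: cmap(i % 10) for i, c in enumerate(clusters)}
        for i, mag in enumerate(ordn.mag_ids):
            c = colors[labels[mag]]
            ax.scatter(*ordn.scores[i, :2], color=c, s=30)
            if annotate:
                ax.annotate(mag, ordn.scores[i, :2], fontsize=7)
        for name, ell in ordn.ellipses.items():
            boundary = ell.boundary()
            ax.plot(boundary[:, 0], boundary[:, 1], color=colors[name], lw=1.2,
                    label=name)
        evr = ordn.explained_variance_ratio
        ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)" if len(evr) > 1 else "PC2")
        if clusters and clusters != [""]:
            ax.legend(fontsize=8)
        return ax
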