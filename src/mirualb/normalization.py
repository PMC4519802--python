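"""Panel-referenced Cq normalization and delta-delta fold-change conversion.

qPCR panels drift between samples (input amount, extraction efficiency,
plate effects).  A per-sample, per-panel normalization factor — the mean Cq
of a fixed set of reference species measured on that panel — absorbs these
additive offsets.  Normalized values are kept on the cycle scale by
centering factors at their grand mean across samples, so a sample whose
references run k cycles high has every measurement shifted down by k.

Fold changes follow the delta-delta convention: FC = 2^(-ddCq) with
ddCq = dCq(miRNA) - dCq(spike-in), the spike-in being an exogenous control
added at a fixed amount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qpcr_io import CqMatrix, ReferencePanel

__all__ = ["NormalizedCq", "FoldChange", "normalize", "delta_delta_fc"]


@dataclass
class NormalizedCq:
    """A CqMatrix after reference normalization.

    ``normalization_factor`` maps (sample_id, panel) to the per-sample mean
    reference Cq (cycles); ``method_tag`` records the centering convention.
    """

    cq: CqMatrix
    normalization_factor: dict[tuple[str, str], float]
    method_tag: str = "panel-mean-centered"

    def __getattr__(self, name):  # delegate matrix accessors
        return getattr(self.cq, name)


@dataclass(frozen=True)
class FoldChange:
    species: str
    delta_delta_cq: float
    fc: float
    reference: str = "UniSp3"


def normalize(cq: CqMatrix, panel: ReferencePanel) -> NormalizedCq:
    """Subtract per-sample, per-panel reference offsets from every Cq.

    For each sample and panel: factor = mean Cq over that panel's reference
    species in that sample (replicate wells averaged first; references below
    the detection limit in a sample are dropped from that sample's factor,
    not imputed).  Normalized Cq = raw Cq − (factor − grand mean of the
    panel's factors).  Non-detected cells keep the censoring sentinel and
    the detection mask is unchanged.
    """
    panel.validate_against(cq)
    out = cq.copy()
    factors: dict[tuple[str, str], float] = {}

    # group reference species by panel label
    by_panel: dict[str, list[str]] = {}
    for ref in panel.reference_species:
        by_panel.setdefault(panel.panel_of(ref), []).append(ref)

    row_of = {s: i for i, s in enumerate(cq.species_ids)}
    species_panels = np.array([panel.panel_of(s) for s in cq.species_ids])

    for pname, refs in by_panel.items():
        fac = np.empty(cq.n_samples)
        for j, sid in enumerate(cq.sample_ids):
            ref_means = []
            for ref in refs:
                rows = [row_of[m] for m in panel.members[ref]]
                vals = [cq.cq[r, j] for r in rows if cq.detected[r, j]]
                if vals:  # replicate wells averaged before factor computation
                    ref_means.append(float(np.mean(vals)))
            if not ref_means:
                raise ValueError(
                    f"sample {sid!r} has no detected reference species on "
                    f"panel {pname!r}"
                )
            fac[j] = float(np.mean(ref_means))
            factors[(sid, pname)] = fac[j]
        offset = fac - fac.mean()  # centered at the grand mean of factors
        rows = np.where(species_panels == pname)[0]
        block = out.cq[np.ix_(rows, np.arange(cq.n_samples))] - offset[None, :]
        det = out.detected[np.ix_(rows, np.arange(cq.n_samples))]
        block[~det] = float(out.max_cycles)  # censored cells untouched
        out.cq[np.ix_(rows, np.arange(cq.n_samples))] = block

    return NormalizedCq(out, factors)


def delta_delta_fc(
    delta_cq_mirna: float,
    delta_cq_spikein: float,
    species: str = "",
    reference: str = "UniSp3",
) -> FoldChange:
    """FC = 2^(-ddCq), ddCq = dCq(miRNA) − dCq(spike-in).

    One cycle earlier threshold crossing (dCq lower by 1) doubles the
    inferred concentration.
    """
    if not (np.isfinite(delta_cq_mirna) and np.isfinite(delta_cq_spikein)):
        raise ValueError("delta-Cq inputs must be finite")
    ddcq = float(delta_cq_mirna - delta_cq_spikein)
    return FoldChange(species, ddcq, float(2.0 ** (-ddcq)), reference)
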