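"""Deleterious/benign verdict from mutant and wild-type feature sets.

Decision rules
--------------
* loss of ribonucleolytic activity: the mutant's His114 side chain spends
  at least ``switch_threshold`` of the trajectory outside its native
  rotamer bin AND a Leu115-mediated hydrogen-bond path from the mutation
  site to His114 persists in at least ``path_threshold`` of the frames
  (the conjunction is configurable via ``Config.ribo_rule``).
* loss of nuclear translocation: the window-mean SASA of the NLS arginines
  31-33 drops by at least ``sasa_reduction_threshold`` relative to wild
  type AND their joint side-chain radius of gyration drops by at least
  ``fold_threshold`` (local folding / close packing).
* destabilized: the window-mean backbone RMSD of the mutant exceeds the
  wild type's by more than ``rmsd_margin``.

A mutation is deleterious when any flag is raised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .features import Config, FeatureSet


class ConfigMismatchError(ValueError):
    """The two feature sets were not computed under the same Config."""


@dataclass
class Verdict:
    loss_ribonucleolytic: bool
    loss_nuclear_translocation: bool
    destabilized: bool
    evidence: dict = field(default_factory=dict)

    @property
    def deleterious(self) -> bool:
        return (
            self.loss_ribonucleolytic
            or self.loss_nuclear_translocation
            or self.destabilized
        )

    def to_dict(self) -> dict:
        return {
            "deleterious": self.deleterious,
            "loss_ribonucleolytic": self.loss_ribonucleolytic,
            "loss_nuclear_translocation": self.loss_nuclear_translocation,
            "destabilized": self.destabilized,
            "evidence": self.evidence,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def report(self, mutation: str | None = None) -> str:
        head = f"Verdict for {mutation}" if mutation else "Verdict"
        lines = [head, "=" * len(head), ""]
        lines.append(
            "Overall call: DELETERIOUS" if self.deleterious
            else "Overall call: BENIGN"
        )
        lines.append("")
        ev = self.evidence

        def _yn(flag: bool) -> str:
            return "YES" if flag else "no"

        r = ev.get("ribonucleolytic", {})
        lines.append(f"Loss of ribonucleolytic activity: {_yn(self.loss_ribonucleolytic)}")
        lines.append(
            f"  His114 conformational switching: fraction "
            f"{r.get('switch_fraction', float('nan')):.3f}"
            f" (threshold {r.get('switch_threshold')})"
        )
        lines.append(
            f"  Leu115-mediated H-bond path site->His114: persistence "
            f"{r.get('path_persistence', float('nan')):.3f}"
            f" (threshold {r.get('path_threshold')})"
        )
        if r.get("best_path"):
            lines.append(f"  Conserved path: {r['best_path']}")
        n = ev.get("nuclear_translocation", {})
        lines.append(f"Loss of nuclear translocation activity: {_yn(self.loss_nuclear_translocation)}")
        lines.append(
            f"  31RRR33 SASA reduction vs WT: "
            f"{n.get('sasa_reduction', float('nan')):.3f}"
            f" (threshold {n.get('sasa_threshold')})"
        )
        lines.append(
            f"  31RRR33 side-chain compaction vs WT: "
            f"{n.get('gyration_reduction', float('nan')):.3f}"
            f" (threshold {n.get('fold_threshold')})"
        )
        s = ev.get("stability", {})
        lines.append(f"Destabilized (backbone RMSD above WT): {_yn(self.destabilized)}")
        lines.append(
            f"  window-mean RMSD mutant {s.get('mut_rmsd', float('nan')):.3f} A vs "
            f"WT {s.get('wt_rmsd', float('nan')):.3f} A "
            f"(margin {s.get('rmsd_margin')} A)"
        )
        return "\n".join(lines) + "\n"


def classify(mut: FeatureSet, wt: FeatureSet, cfg: Config | None = None) -> Verdict:
    """Combine mutant and wild-type feature sets into a verdict.

    Both feature sets must have been computed under the same ``Config``
    (and, if given, ``cfg`` must match it): the thresholds are part of the
    statistics' meaning.
    """
    if mut.config != wt.config:
        raise ConfigMismatchError(
            "mutant and wild-type feature sets were computed under different Configs"
        )
    if cfg is not None and cfg != mut.config:
        raise ConfigMismatchError("cfg differs from the feature sets' Config")
    cfg = mut.config

    switching = mut.his114.switch_fraction >= cfg.switch_threshold
    persistence = mut.path_persistence if mut.path_persistence is not None else 0.0
    has_path = persistence >= cfg.path_threshold
    if cfg.ribo_rule == "and":
        loss_ribo = switching and has_path
    else:
        loss_ribo = switching or has_path

    wt_sasa = wt.nls.mean_total
    sasa_red = (wt_sasa - mut.nls.mean_total) / wt_sasa if wt_sasa > 0 else 0.0
    wt_gyr = wt.nls.mean_gyration
    gyr_red = (wt_gyr - mut.nls.mean_gyration) / wt_gyr if wt_gyr > 0 else 0.0
    loss_nls = (sasa_red >= cfg.sasa_reduction_threshold
                and gyr_red >= cfg.fold_threshold)

    mut_rmsd = mut.rmsd.window_mean(cfg)
    wt_rmsd = wt.rmsd.window_mean(cfg)
    destabilized = (mut_rmsd - wt_rmsd) > cfg.rmsd_margin

    evidence = {
        "ribonucleolytic": {
            "switch_fraction": mut.his114.switch_fraction,
            "switch_threshold": cfg.switch_threshold,
            "native_state": mut.his114.native_state,
            "path_persistence": persistence,
            "path_threshold": cfg.path_threshold,
            "best_path": mut.best_path.label() if mut.best_path else None,
            "rule": cfg.ribo_rule,
        },
        "nuclear_translocation": {
            "sasa_reduction": sasa_red,
            "sasa_threshold": cfg.sasa_reduction_threshold,
            "gyration_reduction": gyr_red,
            "fold_threshold": cfg.fold_threshold,
            "wt_mean_sasa_A2": wt_sasa,
            "mut_mean_sasa_A2": mut.nls.mean_total,
        },
        "stability": {
            "mut_rmsd": mut_rmsd,
            "wt_rmsd": wt_rmsd,
            "rmsd_margin": cfg.rmsd_margin,
        },
    }
    return Verdict(
        loss_ribonucleolytic=loss_ribo,
        loss_nuclear_translocation=loss_nls,
        destabilized=destabilized,
        evidence=evidence,
    )
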