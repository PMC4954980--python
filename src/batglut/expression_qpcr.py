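"""Relative gene expression from qPCR cycle thresholds (Livak method).

Per reaction, dCt = Ct_target - Ct_reference; per species dCt values
are averaged over individuals and runs, and fold changes are
2**-(dCt_species - dCt_calibrator) with the calibrator chosen as the
species with the largest mean dCt (lowest expression), whose fold is
therefore exactly 1.

Tables are pandas DataFrames with columns
``species, individual, run, gene_role, ct`` where ``gene_role`` is
``target`` or ``reference``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CT_COLUMNS = ["species", "individual", "run", "gene_role", "ct"]
ROLES = {"target", "reference"}


@dataclass(frozen=True)
class ExpressionResult:
    delta_ct: dict[str, float]  # per-species mean dCt (cycles)
    folds: dict[str, float]  # per-species fold change, min = 1
    reference_species: str  # the calibrator (fold 1)


def relative_expression(table: pd.DataFrame, efficiency: float = 1.0) -> ExpressionResult:
    """Fold changes by the 2**-ddCt method, rescaled so the
    lowest-expressing species is 1.

    ``efficiency`` is the per-cycle amplification efficiency E; fold
    changes use (1+E)**-ddCt, so the default E = 1 is perfect doubling.
    Replicates are averaged at the dCt level: each (individual, run)
    pair contributes one dCt, and Ct replicates within a reaction (e.g.
    triplicate wells) are averaged per role first.
    """
    if not -1.0 < efficiency:
        raise ValueError("efficiency must exceed -1")
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    bad_roles = set(table["gene_role"]) - ROLES
    if bad_roles:
        raise ValueError(f"unknown gene roles: {sorted(bad_roles)}")

    mean_ct = (
        table.groupby(["species", "individual", "run", "gene_role"])["ct"]
        .mean()
        .unstack("gene_role")
    )
    for species in table["species"].unique():
        sub = mean_ct.loc[species]
        if "reference" not in mean_ct.columns or sub["reference"].isna().any():
            raise ValueError(f"species {species!r} is missing reference-gene rows")
        if "target" not in mean_ct.columns or sub["target"].isna().any():
            raise ValueError(f"species {species!r} is missing target-gene rows")

    dct = (mean_ct["target"] - mean_ct["reference"]).groupby("species").mean()
    calibrator = dct.idxmax()
    base = 1.0 + efficiency
    folds = {sp: float(base ** -(d - dct[calibrator])) for sp, d in dct.items()}
    return ExpressionResult(
        delta_ct={sp: float(d) for sp, d in dct.items()},
        folds=folds,
        reference_species=str(calibrator),
    )


def read_ct_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return table
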