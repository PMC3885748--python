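"""Out-of-sample validation of the published low-dose transfer model.

Evaluates the published equation log10 BCF = -0.098 pH - 0.150 log10 OM
- 1.894 on two independently published field soils (outside the development
panel) and checks the predicted grain-Pb BCFs against the measured values
with the 2-fold agreement criterion. Writes literature_validation.csv.
"""

import math
from pathlib import Path

import pandas as pd

from pbtransfer.bcf_core import BCFRecord
from pbtransfer.cross_species import evaluate_fold_agreement
from pbtransfer.datasets import literature_validation_records, low_pb_model
from pbtransfer.transfer_model import predict_log_bcf

OUTDIR = Path("results")


def main() -> None:
    model = low_pb_model()
    observations = literature_validation_records()
    records = [
        BCFRecord(o.soil.soil_id, o.species, "low", o.measured_bcf,
                  math.log10(o.measured_bcf))
        for o in observations
    ]
    agreement = evaluate_fold_agreement(
        model, records, [o.soil for o in observations], fold=2.0
    )
    rows = [
        {
            "soil_id": o.soil.soil_id,
            "pH": o.soil.ph,
            "om_g_per_kg": o.soil.om,
            "predicted_log_bcf": predict_log_bcf(model, o.soil),
            "predicted_bcf": pred,
            "measured_bcf": meas,
            "fold_deviation": dev,
            "within_2fold": dev <= 2.0,
        }
        for o, (pred, meas), dev in zip(
            observations, agreement.pairs, agreement.fold_deviations
        )
    ]
    OUTDIR.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(rows)
    table.to_csv(OUTDIR / "literature_validation.csv", index=False)
    print(table.to_string(index=False))
    print(f"\ncoverage at 2-fold: {agreement.coverage:.2f}; "
          f"max fold deviation {max(agreement.fold_deviations):.2f}")


if __name__ == "__main__":
    main()
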