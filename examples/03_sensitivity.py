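"""Input-sensitivity table of the coronary flow predictions.

Each coronary derivation input (MAP, CO, branch areas, side compliances) is
varied by +/-20% with the systemic tuning frozen; the table lists the max
relative change in mean branch flow. Mean flows track MAP and CO strongly
and the compliances barely at all (periodic charge conservation).
"""

from coroflow.metrics import run_sensitivity
from coroflow.patients import CohortSpec, generate_synthetic_patient

if __name__ == "__main__":
    pre, _, anatomy = generate_synthetic_patient(CohortSpec(seed=1), 0)
    table = run_sensitivity(pre, anatomy, fraction=0.20)
    print(table.drop(columns="failed").round(2).to_string(index=False))
    print("rows are ordered by influence: pressure and flow inputs dominate, "
          "vessel caliber is next, compliance only reshapes the waveform")
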