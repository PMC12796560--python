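"""Derive the regulatory concentration thresholds (EPC, IPC, IUC).

EPC = dose per 24 h / clearance per 24 h with the typical clearance; IPC
divides by the uncertainty factor 500; IUC multiplies the IPC by the typical
urine-to-plasma ratio.  Candidate screening limits round the IPC/IUC to
whole ng/mL.  Uses the published typical values; if 02 has produced a
fitted prior, the chain is also reported for it.
"""

import json
from pathlib import Path

import flunipk as fp
from flunipk.io import read_prior
from flunipk.limits import candidate_screening_limits

OUT = Path(__file__).resolve().parents[1] / "results"


def report(pop, label):
    lim = fp.derive_limits(pop, dose_mg_per_kg_per_24h=1.1)
    cand = candidate_screening_limits(lim)
    print(f"[{label}] EPC {lim.EPC:.1f} ng/mL  IPC {lim.IPC:.2f} ng/mL  IUC {lim.IUC:.1f} ng/mL"
          f"  -> candidate SLs {cand.plasma_sl:g}/{cand.urine_sl:g} ng/mL (plasma/urine)")
    return {"EPC": lim.EPC, "IPC": lim.IPC, "IUC": lim.IUC,
            "candidate_plasma_sl": cand.plasma_sl, "candidate_urine_sl": cand.urine_sl}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    payload = {"published": report(fp.load_published_prior(), "published prior")}
    fitted = OUT / "fitted_prior.json"
    if fitted.exists():
        payload["fitted"] = report(read_prior(fitted), "fitted prior")
    (OUT / "regulatory_limits.json").write_text(json.dumps(payload, indent=1))
    print(f"-> {OUT/'regulatory_limits.json'}")


if __name__ == "__main__":
    main()
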