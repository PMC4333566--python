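"""Competition-binding curve fitting: wildtype, a weaker mutant and a
binding-dead mutant, three replicate experiments each."""
import numpy as np

from memprobe import DoseResponse, fit_dose_response
from memprobe.assay import fit_experiments
from memprobe.synthetic import gen_dose_response

for compound, pic50 in (("wildtype", 7.1), ("W454A", 6.7)):
    exps = [gen_dose_response(pic50, hill=-1.0, noise_sd=0.01, seed=s,
                              experiment_id=f"{compound}-{s}")[0]
            for s in range(3)]
    fits, summary = fit_experiments(exps)
    print(f"{compound}: pIC50 {summary['mean_pIC50']:.2f} ± "
          f"{summary['sd_pIC50']:.2f} (n = {summary['n']})")

# a mutation that abolishes binding: the competitor displaces nothing
flat = DoseResponse(concentrations=np.logspace(-10, -4, 10),
                    signal=np.full(10, 100.0), experiment_id="dead")
fit = fit_dose_response(flat)
print(f"binding-dead mutant: no_inhibition={fit.no_inhibition} "
      f"(pIC50 undefined)")

# pIC50 = -log10(IC50 in M); 7.1 corresponds to an IC50 of ~79 nM. The
# mean ± SD is over independently fitted replicate experiments, not a
# pooled fit.
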