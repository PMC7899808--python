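"""Inter-coder agreement on qualitative feedback codes.

Two coders assign one code per response; raw agreement is the fraction of
identical assignments and Cohen's kappa corrects it for the agreement two
independent coders would reach by chance given their code frequencies.
"""

from breezesim import cohen_kappa

codes_a = ["guidance", "gamification", "relaxation", "to_add", "guidance",
           "visualization", "gamification", "relaxation", "guidance",
           "to_add", "visualization", "guidance"]
codes_b = ["guidance", "to_add", "relaxation", "to_add", "guidance",
           "visualization", "gamification", "relaxation", "guidance",
           "to_add", "visualization", "biofeedback"]

result = cohen_kappa(codes_a, codes_b)
print(f"raw agreement p_o = {result.p_o:.3f}")
print(f"Cohen kappa       = {result.kappa:.3f}")

# kappa < p_o always: some matches are expected by chance alone.  Values
# above ~0.8 are conventionally read as almost perfect agreement.
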