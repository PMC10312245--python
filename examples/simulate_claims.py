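"""Generate a small synthetic claims world and inspect its tables.

The generator emulates a regional outpatient sector: a practice roster with
entry/exit and a minority of integrated practices (IPs), a growing patient
population with gamma-distributed Charlson scores, and visit-level claims in
which patients favour practices in their own community block — with IPs
gaining attachment weight each year (the latent cooperation drift).
"""

import coopnet as cn

cfg = cn.test_scale_config(n_practices_initial=40, n_patients_initial=800,
                           n_years=6, seed=7)
practices = cn.generate_practices(cfg)
patients = cn.generate_patients(cfg)
claims = cn.generate_claims(cfg, practices, patients)

print(f"practices: {len(practices)} distinct over {cfg.n_years} years "
      f"({practices['is_ip'].sum()} integrated)")
print(f"patient-years: {len(patients)}  (mean Charlson "
      f"{patients['charlson_score'].mean():.2f})")
print(f"claims rows: {len(claims)}  "
      f"({(claims['visit_type'] == 'emergency').mean():.1%} emergency)")
print()
print(claims.head().to_string(index=False))
print()
print("Each row is one patient visit; emergency visits and visits to "
      "anaesthesiology/radiology/neuropathology will be dropped by the "
      "network filters downstream.")
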