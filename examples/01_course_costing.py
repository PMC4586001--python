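"""Micro-cost one rehabilitation course per arm from the shipped fixtures.

Staff formal hours are loaded by 1.5 for non-productive time, valued at
gross wages, the expert patient (lay educator) at a flat pensioner net
wage, and 21 % hospital overhead is added before dividing by the 10
patients a course serves on average.
"""

import rehabcea as r

catalogue, _, specs = r.load_default_costing()

for arm in ("lc", "standard"):
    c = r.course_cost(specs[arm], catalogue)
    print(f"\n{arm} course ({c.patients_per_course} patients)")
    print(f"  nurse:    {c.nurse_formal_h:.0f} h formal -> {c.nurse_loaded_h:.0f} h loaded "
          f"= {c.nurse_total:,} DKK")
    print(f"  physio:   {c.physio_formal_h:.0f} h formal -> {c.physio_loaded_h:.0f} h loaded "
          f"= {c.physio_total:,} DKK")
    print(f"  expert patient: {c.expert_time_h:.0f} h + transport = {c.expert_total:,} DKK")
    print(f"  overhead (21 %): {c.overhead:,} DKK")
    print(f"  total per course: {c.total_per_course:,} DKK "
          f"-> {c.cost_per_patient:,} DKK per patient")

lc = r.course_cost(specs["lc"], catalogue)
std = r.course_cost(specs["standard"], catalogue)
print(f"\nincremental intervention cost: {lc.cost_per_patient - std.cost_per_patient:,} "
      "DKK per patient")
# The learning-and-coping additions (interviews, team evaluations, expert
# patient) cost an extra 2,072 DKK per patient on top of standard education.
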