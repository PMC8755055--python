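"""Age-unit conventions shared across the package.

All ages are stored in days; "months" always means days / 30.44, the same
constant used to scale length velocity to cm/month. Using a single
conversion constant everywhere keeps velocities, spline knots (placed in
months), and age bins mutually consistent.
"""

DAYS_PER_MONTH: float = 30.44


def days_to_months(age_days):
    return age_days / DAYS_PER_MONTH


def months_to_days(age_months):
    return age_months * DAYS_PER_MONTH
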