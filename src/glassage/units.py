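"""Unit helpers and physical constants.

Canonical internal units are kelvin, seconds, J·g⁻¹·K⁻¹ and J·g⁻¹;
degrees Celsius, minutes and hours are accepted only at I/O boundaries.
Scan rates are carried in K·min⁻¹ (the unit every DSC method file uses)
and converted to K·s⁻¹ where an integral needs them.
"""

GAS_CONSTANT = 8.314462618  # J·mol⁻¹·K⁻¹

ZERO_CELSIUS = 273.15  # K

SECONDS_PER_MINUTE = 60.0
SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0


def celsius_to_kelvin(t_c):
    return t_c + ZERO_CELSIUS


def kelvin_to_celsius(t_k):
    return t_k - ZERO_CELSIUS


def per_minute_to_per_second(rate):
    """Convert a scan rate from K·min⁻¹ to K·s⁻¹."""
    return rate / SECONDS_PER_MINUTE


def hours_to_seconds(t_h):
    return t_h * SECONDS_PER_HOUR


def seconds_to_hours(t_s):
    return t_s / SECONDS_PER_HOUR


def days_to_seconds(t_d):
    return t_d * SECONDS_PER_DAY
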