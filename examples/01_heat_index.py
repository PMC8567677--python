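"""Heat Index: apparent temperature from air temperature and humidity.

The Heat Index combines air temperature (deg F) and relative humidity (%)
through the Rothfusz regression polynomial, with the standard NWS
adjustments for very dry or very humid conditions and a simple linear
formula below 80 deg F.
"""

from heatvuln import c_to_f, f_to_c, heat_index

points = [
    (90.0, 60.0, "polynomial branch: a humid summer afternoon"),
    (85.0, 5.0, "low-humidity adjustment: desert-dry air"),
    (82.0, 95.0, "high-humidity adjustment: tropical air"),
    (70.0, 50.0, "below 80 F: simple formula, HI ~ T"),
]

print(f"{'T (F)':>7} {'RH (%)':>7} {'HI (F)':>8} {'HI (C)':>8}  note")
for t, r, note in points:
    hi = heat_index(t, r)
    print(f"{t:7.1f} {r:7.1f} {hi:8.2f} {f_to_c(hi):8.2f}  {note}")

t_c = 33.0  # a 33 C Florida day at 60% humidity
hi_c = f_to_c(heat_index(c_to_f(t_c), 60.0))
print(f"\nA {t_c:.0f} C day at 60% RH feels like {hi_c:.1f} C: "
      "the gap is the extra physiological load of humid heat.")
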