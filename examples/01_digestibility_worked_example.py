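"""Digestibility arithmetic on published line means.

Chains air-dry recovery x fresh manure weight -> manure DM, feed intake x
feed DM content -> feed DM, and their ratio -> the dry-matter
digestibility coefficient; then the feed conversion ratio from intake and
egg mass. Inputs are the reported means of two White Leghorn layer lines.
"""

from layerdig import dc_dry_matter, fcr, feed_dm_amount, manure_dm_amount

# line B: eats 122.8 g/day, voids 146.6 g fresh manure/day, of which
# 260.2 g/kg remains after air-drying; the diet is 900 g DM/kg as-fed
manure_dm_b = manure_dm_amount(adm=260.2, dmw=146.6)
manure_dm_a = manure_dm_amount(adm=252.4, dmw=121.6)
feed_dm_b = feed_dm_amount(dfc=122.8, feed_dm=900.0)
dc_dm_b = dc_dry_matter(manure_dm_b, feed_dm_b)
fcr_b = fcr(dfc=122.8, em=53.8, period_days=7)

print(f"manure DM, line B : {manure_dm_b:.1f} g/day")
print(f"manure DM, line A : {manure_dm_a:.1f} g/day")
print(f"feed DM, line B   : {feed_dm_b:.2f} g/day")
print(f"DC_DM, line B     : {dc_dm_b:.1f} %")
print(f"FCR, line B       : {fcr_b:.1f}")
print()
print("DC_DM 65.5 % means line B digests about two thirds of ingested dry")
print("matter; FCR 2.3 means 2.3 g of feed per gram of egg mass produced.")
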