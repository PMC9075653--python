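"""Pure-arithmetic CEA: feed published aggregate ledgers through the
economics layer (no simulation)."""
from pesim import econ
from pesim.config import EconConfig

params = EconConfig()   # 3% discounting, WTP $8,597/DALY

# published scenario ledgers for a Mexico City school-PE analysis
no_pe = econ.LedgerRow(dalys=487_153.21, direct_medical=4_010_214_129,
                       productivity=518_696_480)
pe = econ.LedgerRow(dalys=483_366.01, direct_medical=3_981_794_993,
                    productivity=515_937_633, program_cost=50_333_172)

r = econ.cea_from_ledgers(no_pe, pe, params)
print(f"DALYs averted:        {r.delta_daly:,.2f}")
print(f"third-party ICER:     ${r.icer_third_party.value:,.0f} /DALY averted")
print(f"societal ICER:        ${r.icer_societal.value:,.0f} /DALY averted")
print(f"cost-effective (<= ${params.wtp_per_daly:,.0f}/DALY): "
      f"{r.icer_third_party.cost_effective}")

pe_meet = econ.LedgerRow(dalys=476_034.37, direct_medical=3_928_336_046,
                         productivity=510_527_231, program_cost=50_333_172)
r2 = econ.cea_from_ledgers(no_pe, pe_meet, params)
print(f"\nguideline-meeting ledger:")
print(f"net direct-medical savings: ${r2.net_direct_savings/1e6:.1f}M")
print(f"net societal savings:       ${r2.net_societal_savings/1e6:.1f}M")
print(f"max cost remaining cost-saving (societal):    "
      f"${r2.max_cost_cost_saving['societal']/1e6:.1f}M")
print(f"max cost remaining cost-effective (societal): "
      f"${r2.max_cost_cost_effective['societal']/1e6:.1f}M")

# Expected output: ICERs $5,786 and $5,058 per DALY averted; net savings
# $31.5M direct / $39.7M societal; budget headroom $90.0M cost saving and
# $185.6M cost-effective from the societal perspective.
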