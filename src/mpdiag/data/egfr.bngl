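# EGFR early signaling example: ligand binding, dimerization,
# transphosphorylation and dephosphorylation over two tyrosines.
begin parameters
  kon 1
  kdim 1
  kp 1
  kd 1
end parameters
begin molecule types
  EGF(site)
  EGFR(ecd,tmd,Y1~U~P,Y2~U~P)
end molecule types
begin seed species
  EGF(site) 1
  EGFR(ecd,tmd,Y1~U,Y2~U) 1
  EGFR(ecd,tmd,Y1~U,Y2~P) 1
  EGFR(ecd,tmd,Y1~P,Y2~U) 1
  EGFR(ecd,tmd,Y1~P,Y2~P) 1
end seed species
begin reaction rules
  R1: EGF(site) + EGFR(ecd,tmd) -> EGF(site!1).EGFR(ecd!1,tmd) kon
  R2: EGFR(Y1~P) -> EGFR(Y1~U) kd
  R3: EGFR(Y2~P) -> EGFR(Y2~U) kd
  R4: EGFR(ecd!+,tmd) + EGFR(ecd!+,tmd) -> EGFR(ecd!+,tmd!1).EGFR(ecd!+,tmd!1) kdim
  R5: EGFR(tmd!1).EGFR(tmd!1,Y1~U) -> EGFR(tmd!1).EGFR(tmd!1,Y1~P) kp
  R6: EGFR(tmd!1).EGFR(tmd!1,Y2~U) -> EGFR(tmd!1).EGFR(tmd!1,Y2~P) kp
end reaction rules
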