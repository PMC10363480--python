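; SYNTHETIC stand-in for the study's peptide panel (13 antimicrobial cores,
; two TP preproteins with declared cleavage sites, two random controls).
; Generated with peptarget.simulate primitives, seed 20230555. Sequences are
; NOT the real peptides; ids/roles/cleavage arithmetic follow the study layout.
>B2I role=HA_RAMP family=brevinin-2
IKKLIKKVIKIISKLATKFNQALST
>MII role=HA_RAMP family=magainin
IKKLLNGFIQVLKTLAKNLKKII
>R2G role=HA_RAMP family=ranatuerin-2
AKKAFQSLLSFLKGFLKSLGSIAGGIFK
>DS4 role=HA_RAMP family=dermaseptin
IKTFVKTAVKLLKSVFQKANKVIKKIVK
>DDM role=HA_RAMP family=dermadistinctin
LSKILQQIAGAVSGVIKKFSSLIKKVLKIIKGI
>B1E role=HA_RAMP family=brevinin-1
VGKIVKTIVKIVQKFVSSIQKFFT
>CP3 role=HA_RAMP family=cecropin
PTPTAKKLVKNIFKFIKSAISKIKGIIKTIAKILKKAAG
>S1D role=HA_RAMP family=sarcotoxin
IKKVAGSVFNFLQKIASKAKSLVNSFLQALTQLLKKLKK
>E1S role=HA_RAMP family=esculentin-1
RRTSRGRSTVTNLITKIAKLLKNIFKSLKKAISQIINLINKIATKI
>LCA role=HA_RAMP family=leucocin
ATAAASGGLKKALGGVAGVLKSIATSIKGVLKKIFKL
>SIM role=HA_RAMP family=moricin
RPAGRGVKTFFKKLFKIFKKLVKQVSTILKQLISIISSILNK
>B15 role=HA_RAMP family=bacillocin
STRGRARRRPITNILKQLFKILKKALSTIKKFFKSIAGIA
>EHF role=HA_RAMP family=enterocin
TAPPPATTTIKGIAKKAFNIVKGLFSNAKKLLKTVFNFATNLFN
>RCA1-cTP role=cTP cleavage=45 family=rubisco-activase
RSRAPSATTPARRTPLGRALRRILGLAGQIFGRFTRAGATPSRARSVATVDSDGQVALEKLTLKELAE
>CAG2-mTP role=mTP cleavage=36 family=gamma-carbonic-anhydrase
ATRIARTFVNLIRRFVRTLQRLIRSFGPPGAGTSGSQQTTSDDKTVEKVVQAVQDAADA
>RP1 role=RANDOM family=random
VHETDSDMDIFACAERPGSQYWADACFEPE
>RP2 role=RANDOM family=random
LRIARNKSEDSRADSITGTSPNFAHISFED
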