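{
  "name": "hsa_toy (synthetic stand-in library; real elemental formulas, toy pathway memberships)",
  "ion_mode": "both",
  "compounds": [
    {"id": "C00187", "name": "Cholesterol", "formula": "C27H46O"},
    {"id": "C00695", "name": "Cholic acid", "formula": "C24H40O5"},
    {"id": "C02528", "name": "Chenodeoxycholate", "formula": "C24H40O4"},
    {"id": "C04483", "name": "Deoxycholate", "formula": "C24H40O4"},
    {"id": "C03990", "name": "Lithocholate", "formula": "C24H40O3"},
    {"id": "C01921", "name": "Glycocholate", "formula": "C26H43NO6"},
    {"id": "C05466", "name": "Glycochenodeoxycholate", "formula": "C26H43NO5"},
    {"id": "C05122", "name": "Taurocholate", "formula": "C26H45NO7S"},
    {"id": "C03594", "name": "7alpha-Hydroxycholesterol", "formula": "C27H46O2"},
    {"id": "C17336", "name": "3beta,7alpha-Dihydroxy-5-cholestenoate", "formula": "C27H44O4"},
    {"id": "CE2202", "name": "23S,25,26-Trihydroxyvitamin D3", "formula": "C27H44O4"},
    {"id": "C00246", "name": "Butanoate", "formula": "C4H8O2"},
    {"id": "C91001", "name": "2-Butynoate", "formula": "C4H4O2"},
    {"id": "C00246X", "name": "Crotonate", "formula": "C4H6O2"},
    {"id": "C01089", "name": "3-Hydroxybutanoate", "formula": "C4H8O3"},
    {"id": "C00164", "name": "Acetoacetate", "formula": "C4H6O3"},
    {"id": "C06006", "name": "(S)-2-Aceto-2-hydroxybutanoate", "formula": "C6H10O4"},
    {"id": "C01412", "name": "Butanal", "formula": "C4H8O"},
    {"id": "C06142", "name": "1-Butanol", "formula": "C4H10O"},
    {"id": "C00232", "name": "Succinate semialdehyde", "formula": "C4H6O3"},
    {"id": "C00989", "name": "4-Hydroxybutanoate", "formula": "C4H8O3"},
    {"id": "C00489", "name": "Glutarate", "formula": "C5H8O4"},
    {"id": "C05443", "name": "Vitamin D3", "formula": "C27H44O"},
    {"id": "C01561", "name": "Calcidiol", "formula": "C27H44O2"},
    {"id": "C01673", "name": "Calcitriol", "formula": "C27H44O3"},
    {"id": "C91002", "name": "24,25-Dihydroxyvitamin D3", "formula": "C27H44O3"},
    {"id": "C01164", "name": "7-Dehydrocholesterol", "formula": "C27H44O"},
    {"id": "C00249", "name": "Palmitate", "formula": "C16H32O2"},
    {"id": "C01530", "name": "Stearate", "formula": "C18H36O2"},
    {"id": "C00712", "name": "Oleate", "formula": "C18H34O2"},
    {"id": "C01595", "name": "Linoleate", "formula": "C18H32O2"},
    {"id": "C06424", "name": "Myristate", "formula": "C14H28O2"},
    {"id": "C02679", "name": "Laurate", "formula": "C12H24O2"},
    {"id": "C01585", "name": "Hexanoate", "formula": "C6H12O2"},
    {"id": "C06423", "name": "Octanoate", "formula": "C8H16O2"},
    {"id": "C02477", "name": "alpha-Tocopherol", "formula": "C29H50O2"},
    {"id": "C02483", "name": "gamma-Tocopherol", "formula": "C28H48O2"},
    {"id": "C91003", "name": "alpha-CEHC", "formula": "C16H22O4"},
    {"id": "C91004", "name": "gamma-CEHC", "formula": "C15H20O4"},
    {"id": "C91005", "name": "alpha-Tocopherolquinone", "formula": "C29H50O3"},
    {"id": "C14153", "name": "alpha-Tocotrienol", "formula": "C29H44O2"},
    {"id": "C00751", "name": "Squalene", "formula": "C30H50"},
    {"id": "C01724", "name": "Lanosterol", "formula": "C30H50O"},
    {"id": "C00418", "name": "Mevalonate", "formula": "C6H12O4"},
    {"id": "C00448", "name": "Farnesyl diphosphate", "formula": "C15H28O7P2"},
    {"id": "C00341", "name": "Geranyl diphosphate", "formula": "C10H20O7P2"},
    {"id": "C00129", "name": "Isopentenyl diphosphate", "formula": "C5H12O7P2"},
    {"id": "C01802", "name": "Desmosterol", "formula": "C27H44O"},
    {"id": "C01189", "name": "Lathosterol", "formula": "C27H46O"},
    {"id": "C00535", "name": "Testosterone", "formula": "C19H28O2"},
    {"id": "C00280", "name": "Androstenedione", "formula": "C19H26O2"},
    {"id": "C00951", "name": "Estradiol-17beta", "formula": "C18H24O2"},
    {"id": "C00468", "name": "Estrone", "formula": "C18H22O2"},
    {"id": "C01227", "name": "Dehydroepiandrosterone", "formula": "C19H28O2"},
    {"id": "C05141", "name": "Estriol", "formula": "C18H24O3"},
    {"id": "C03917", "name": "Dihydrotestosterone", "formula": "C19H30O2"},
    {"id": "C00523", "name": "Androsterone", "formula": "C19H30O2"},
    {"id": "C00272", "name": "Tetrahydrobiopterin", "formula": "C9H15N5O3"},
    {"id": "C00268", "name": "Dihydrobiopterin", "formula": "C9H13N5O3"},
    {"id": "C06313", "name": "Biopterin", "formula": "C9H11N5O3"},
    {"id": "C05926", "name": "Neopterin", "formula": "C9H11N5O4"},
    {"id": "C00835", "name": "Sepiapterin", "formula": "C9H11N5O3"},
    {"id": "C00715", "name": "Pterin", "formula": "C6H5N5O"}
  ],
  "pathways": [
    {"id": "P001", "name": "Bile acid biosynthesis",
     "cpds": ["C00187", "C00695", "C02528", "C04483", "C03990", "C01921",
              "C05466", "C05122", "C03594", "C17336", "CE2202"]},
    {"id": "P002", "name": "Butyrate metabolism",
     "cpds": ["C00246", "C91001", "C00246X", "C01089", "C00164", "C06006",
              "C01412", "C06142", "C00232", "C00989", "C00489"]},
    {"id": "P003", "name": "Vitamin D3 metabolism",
     "cpds": ["C05443", "C01561", "C01673", "C91002", "C01164", "CE2202"]},
    {"id": "P004", "name": "Fatty acid metabolism",
     "cpds": ["C00249", "C01530", "C00712", "C01595", "C06424", "C02679",
              "C01585", "C06423"]},
    {"id": "P005", "name": "Vitamin E metabolism",
     "cpds": ["C02477", "C02483", "C91003", "C91004", "C91005", "C14153"]},
    {"id": "P006", "name": "Squalene and cholesterol biosynthesis",
     "cpds": ["C00751", "C01724", "C00418", "C00448", "C00341", "C00129",
              "C01802", "C01189", "C00187"]},
    {"id": "P007", "name": "Androgen and estrogen biosynthesis and metabolism",
     "cpds": ["C00535", "C00280", "C00951", "C00468", "C01227", "C05141",
              "C03917", "C00523"]},
    {"id": "P008", "name": "Biopterin metabolism",
     "cpds": ["C00272", "C00268", "C06313", "C05926", "C00835", "C00715"]}
  ]
}
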