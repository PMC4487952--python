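indicator_id,layer,polarity,description
C1,B1,negative,Population density
C2,B1,positive,Employment rate
C3,B1,negative,Engel coefficient
C4,B1,positive,Residential land use rate
C5,B1,positive,Year-end road area
C6,B1,positive,Per capita arable land
C7,B1,positive,Urbanization rate
C8,B2,positive,Green coverage
C9,B2,positive,Comprehensive utilization of industrial solid wastes
C10,B2,positive,Urban industrial wastewater discharge compliance rate
C11,B2,negative,Environmental investment index
C12,B2,positive,Centralized sewage treatment rate
C13,B2,positive,Hazard-free treatment rate of household garbage
C14,B3,positive,GDP
C15,B3,positive,Industrial output
C16,B3,positive,Proportion of tertiary industry
C17,B3,positive,Total retail sales of social consumer goods
C18,B3,negative,Intermediate consumption of primary industry
C19,B3,negative,Energy consumption per unit industrial added value
C20,B3,positive,Effective irrigation area of arable land ratio
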