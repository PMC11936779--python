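# Categories and sub-categories where total sugars stands in for free
# sugars (essentially all sugars in these products are free sugars).
override_categories:
  - Juice Drinks
  - Carbonated Soft Drinks
  - Sweeteners & Sugar
  - Sugar & Gum Confectionery
override_subcategories:
  - Flavoured Water
  - Honey
  - Syrups
  - Ready To Drink (Iced) Tea
  - Water Based Ice Lollies, Pops & Sorbets
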