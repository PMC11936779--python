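# Default English sugar-ingredient lexicon.
#
# Each entry is a case-insensitive regular expression matched against one
# parsed ingredient name.  `added_sugar` covers caloric sweeteners added in
# processing (FDA sense) plus honey, syrups, fruit juice concentrates (free
# sugars in the WHO sense); `dairy` and `fruit_veg` mark naturally occurring
# sugar sources.  `exclusions` veto a match on the same ingredient name
# (non-caloric sweeteners, sugar alcohols, "sugar free" phrasing).
# The list is data, not code: enrich it whenever necessary.
added_sugar:
  - '\bsugars?\b'
  - '\bcane sugar\b'
  - '\bcane juice\b'
  - '\bevaporated cane\b'
  - '\bbrown sugar\b'
  - '\braw sugar\b'
  - '\bturbinado\b'
  - '\bdemerara\b'
  - '\bmuscovado\b'
  - '\bicing sugar\b'
  - '\bpowdered sugar\b'
  - '\bcaster sugar\b'
  - '\binvert(ed)? sugar\b'
  - '\bbeet sugar\b'
  - '\bcoconut sugar\b'
  - '\bpalm sugar\b'
  - '\bdate sugar\b'
  - '\bmaple sugar\b'
  - '\bhigh[- ]fructose corn syrup\b'
  - '\bhfcs\b'
  - '\bcorn syrup\b'
  - '\bglucose([- ]fructose)? syrup\b'
  - '\bfructose([- ]glucose)? syrup\b'
  - '\brice syrup\b'
  - '\bmalt syrup\b'
  - '\bmaple syrup\b'
  - '\bgolden syrup\b'
  - '\bagave( syrup| nectar)?\b'
  - '\bcarob syrup\b'
  - '\bsorghum( syrup)?\b'
  - '\brefiner''?s? syrup\b'
  - '\bsyrup\b'
  - '\bhoney\b'
  - '\bmolasses\b'
  - '\btreacle\b'
  - '\bdextrose\b'
  - '\bglucose\b'
  - '\bfructose\b'
  - '\bsucrose\b'
  - '\bmaltose\b'
  - '\bgalactose\b'
  - '\btrehalose\b'
  - '\bisoglucose\b'
  - '\bbarley malt( extract)?\b'
  - '\bmalt extract\b'
  - '\bcaramel\b'
  - '\b(fruit|apple|grape|pear|orange|pineapple|date) juice concentrate\b'
  - '\bconcentrated (fruit|apple|grape|pear) juice\b'
  - '\bfruit concentrate\b'
  - '\bdate (paste|syrup)\b'
  - '\bjaggery\b'
  - '\bpanela\b'
  - '\bpiloncillo\b'
  - '\bsweetened condensed milk\b'
  - '\bdulce de leche\b'
  - '\bhoney powder\b'
  - '\bglucose solids\b'
  - '\bcorn sweetener\b'
dairy:
  - '\bmilk\b(?! thistle)'
  - '\bskimmed? milk\b'
  - '\bwhole milk\b'
  - '\bmilk powder\b'
  - '\bmilk solids\b'
  - '\bwhey\b'
  - '\bwhey (powder|solids|protein concentrate)\b'
  - '\byog(h?)urt\b'
  - '\bcream\b(?! of tartar)'
  - '\bbuttermilk\b'
  - '\bcheese\b'
  - '\bquark\b'
  - '\bkefir\b'
  - '\bcasein(ate)?s?\b'
  - '\blactoserum\b'
  - '\blactose\b(?![- ]free)'
fruit_veg:
  - '\bapples?\b'
  - '\bapple (puree|pulp|juice|sauce)\b'
  - '\bpears?\b'
  - '\bbananas?\b'
  - '\bstrawberr(y|ies)\b'
  - '\braspberr(y|ies)\b'
  - '\bblueberr(y|ies)\b'
  - '\bblackberr(y|ies)\b'
  - '\bcranberr(y|ies)\b'
  - '\bcherr(y|ies)\b'
  - '\bgrapes?\b'
  - '\braisins?\b'
  - '\bsultanas?\b'
  - '\bcurrants?\b'
  - '\bdates?\b(?! (sugar|paste|syrup))'
  - '\bfigs?\b'
  - '\bprunes?\b'
  - '\bapricots?\b'
  - '\bpeach(es)?\b'
  - '\bplums?\b'
  - '\bmango(es)?\b'
  - '\bpineapples?\b'
  - '\boranges?\b'
  - '\blemons?\b'
  - '\blimes?\b'
  - '\bgrapefruits?\b'
  - '\bkiwi\b'
  - '\bmelons?\b'
  - '\bwatermelons?\b'
  - '\bpapayas?\b'
  - '\bpassion ?fruit\b'
  - '\bcoconut\b(?! (oil|sugar))'
  - '\bfruit (puree|pulp|pieces|juice)\b'
  - '\b(apple|orange|grape|pineapple|mango|pear) juice\b(?! concentrate)'
  - '\btomato(es)?\b'
  - '\btomato (paste|puree|concentrate)\b'
  - '\bcarrots?\b'
  - '\bbeetroots?\b'
  - '\bsweet ?potato(es)?\b'
  - '\bpumpkins?\b'
  - '\bpeas?\b'
  - '\bsweet ?corn\b'
  - '\bonions?\b'
exclusions:
  - '\bsucralose\b'
  - '\baspartame\b'
  - '\bacesulfame\b'
  - '\bsaccharin\b'
  - '\bstevia\b'
  - '\bsteviol\b'
  - '\bmonk fruit\b'
  - '\bneotame\b'
  - '\badvantame\b'
  - '\bcyclamate\b'
  - '\bthaumatin\b'
  - '\bxylitol\b'
  - '\bsorbitol\b'
  - '\bmaltitol\b'
  - '\berythritol\b'
  - '\bmannitol\b'
  - '\bisomalt\b'
  - '\blactitol\b'
  - '\bpolydextrose\b'
  - '\bsugar[- ]free\b'
  - '\blactose[- ]free\b'
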